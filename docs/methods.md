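# Methods

## Scope and model

The package assesses the druggability of a *single, ligand-seeded binding
region* on a protein–protein interface.  The druggability score is

    Dscore = 0.094·√n + 0.60·e − 0.324·p

with n the site-point count, e the enclosure factor and p the
hydrophilicity factor.  The score is evaluated exactly as printed, without
clamping; classification uses half-open intervals closed at the lower
edge: very druggable [1.0, ∞), druggable [0.75, 1.0), moderately druggable
[0.5, 0.75), difficult [0, 0.5).  A site that cannot be detected (ND) is
always classified difficult; where a plot or correlation needs a number
for an ND target the caller may request zero-imputation, but medians never
include such surrogates.  Halgren's general-purpose scheme is implemented
as difficult [0, 0.8), druggable [0.8, 1.0), very druggable [1.0, ∞); the
"greater than 1" cutoff is realized as ≥ 1.0 for internal consistency
between the two schemes.

## The descriptor engine

The engine defining n, e and p is an open surrogate for proprietary
pocket-mapping tools.  It shares the three named quantities and their
qualitative meaning, but **numerical identity with any proprietary
implementation on deposited structures is not claimed and not tested**.
The engine is instead validated by construction: exact equivalence with an
independent brute-force recomputation on small synthetic cavities,
monotonicity in cavity depth/rim/polar lining, the ND outcome on flat
interfaces, and rigid-motion invariance.

Definitions (all lengths in Å; defaults in parentheses):

* **Candidate grid.** An axis-aligned lattice at `grid_spacing` (1.0)
  anchored at the seeding ligand's centroid, covering the ligand bounding
  box expanded by `region_margin` (6.0).  Points within vdW radius +
  `probe_radius` (1.4) of any protein heavy atom are removed.  Anchoring
  the lattice at the ligand centroid makes every descriptor exactly
  invariant under rigid translation of the complex and independent of the
  deposition frame.
* **Enclosure.** For each candidate point, the fraction of 162 fixed ray
  directions (icosphere vertices, two subdivisions; `ray_subdivisions` 2)
  along which a protein heavy-atom vdW sphere is intersected within
  `ray_length` (10.0), using exact ray–sphere tests.  Bondi radii are
  used throughout; hydrogens are ignored everywhere, so all descriptors
  are heavy-atom based.
* **Site.** Candidate points with enclosure ≥ `enclosure_threshold` (0.5)
  are clustered by 26-neighbour lattice connectivity; the connected
  component closest to the ligand centroid is the site (ties: larger
  component, then lexicographic lattice order).  n is its cardinality and
  e the mean enclosure over its points.  Components smaller than
  `min_site_points` (5) are noise: the result is ND.  The threshold sits
  safely below the smallest reported real pockets (8–9 site points).
* **Hydrophilicity.** Protein heavy atoms within `contact_cutoff` (4.0) of
  any site point are the lining; p = `hydrophilicity_scale` (k_p = 1.6) ×
  (polar weight / lining size), where N and O count 1 and charged
  side-chain N/O (Arg NE/NH1/NH2, Lys NZ, Asp OD1/OD2, Glu OE1/OE2) count
  2.  k_p maps the dimensionless polar fraction onto the empirically
  observed range of philic scores (≈ 0.06–1.6 across surveyed targets);
  it is a declared calibration constant, configurable, and flagged for
  re-calibration if comparability with any specific external tool is ever
  needed.  Reported p values above 1 are therefore legitimate (fully polar
  linings reach k_p).

Determinism: the ray set is fixed and lexicographically ordered, nothing
is random, and identical inputs give bit-identical descriptors.

### Numerical behaviour and tolerances

Rotations are not lattice symmetries, so descriptors fluctuate with
orientation by discretization noise.  On a well-resolved pocket (a few
grid cells wide in every direction after probe clearance) the fluctuation
stays within |Δn|/n ≤ 0.15 and |Δe| ≤ 0.05 over random rigid motions;
pockets whose free interior is ~1 grid cell wide (e.g. a 4 Å-radius well
probed at 1.7 + 1.4 Å clearance) alias more strongly, which is a property
of any lattice method at its resolution limit.  The 162-direction
enclosure overestimates the continuous solid angle by up to ~0.02–0.03
near a flat horizon; refining to 642 directions converges to within 0.01
of a Monte-Carlo estimate.  The default stays at 162 directions as the
accepted cost/accuracy point.

## Curation and superposition

Curation keeps the chain whose minimum heavy-atom distance to the ligand
is smallest (contact cutoff 5.0 Å, ties by chain label), strips waters and
hetero residues except an explicitly retained ligand, resolves alternate
locations to the highest-occupancy conformer (ties: first listed),
preserves insertion codes, and treats MSE-like modified residues as
protein.  Structures are expected to arrive with complete heavy atoms;
rebuilding missing atoms or loops and protonation are upstream concerns.
When one chain contains several copies of the seeding ligand the library
raises an error rather than guessing which copy defined the pocket.

Apo and protein/peptide-bound structures carry no pocket identifier, so
each is globally aligned (BLOSUM62, gap open 10 / extend 1, a gap of
length L costing open + (L−1)·extend; unknown residues score 0) to a
ligand-bound reference of the same protein.  Cα atoms of aligned residue
pairs (≥ 20 required) are fitted with the Kabsch algorithm
(reflection-corrected SVD), and the **inverse** transform moves the
reference ligand into the target's native frame — the target structure is
never moved.  Optional iterative trimming (drop pairs beyond 2 SD, at most
3 rounds, never below 20 pairs) is off by default.  Ties between
co-optimal alignments are broken by the aligner's canonical enumeration
order, which is deterministic.

## Drug-likeness

Ro5 violations are counted against Mwt ≤ 500 Da, LogP ≤ 5, HBD ≤ 5,
HBA ≤ 10; "drug-like (Ro5)" means zero violations (a configurable switch
allows the ≤ 1 reading used by some descriptor suites).  **Ro5-1** is the
relaxed PPI rule: drug-like iff at most one violation — so Ro5 compliance
implies Ro5-1 compliance, and audits report both.  QED is the weighted
geometric mean of eight desirability values computed with the published
asymmetric-double-sigmoid coefficients (Bickerton et al.'s quantitative
estimate of drug-likeness); desirabilities are floored at 1e-6 before the
logarithm.  The default weight set is unweighted (all 1), since property
tables in the wild rarely state which variant they used; the canonical
mean-weight set is available by flag, and the in-house evaluation is
cross-checked term by term against an independent implementation in the
test suite.  The Rule-of-Four profile (Mwt > 400, ALogP > 4, HBA > 4,
rings > 4, strict) is descriptive only and reported alongside the rules.
The module consumes property tables; computing properties from SMILES/SDF
is a pluggable backend, deliberately outside the core so the package works
without a chemistry toolkit.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline needs, deterministically
from spec + seed, with manifests holding the ground truth.

* **Cavity slabs** place one-atom residues on a cubic lattice (default
  spacing 2.0 Å) and carve a flat-bottomed cylindrical well (radius,
  depth); optional rim rings stack above the mouth, and a chosen fraction
  of the cavity-lining atoms become N/O (nested roster, so raising the
  fraction only adds polar sites).  Residue identities are drawn uniformly
  per lattice site, giving informative sequences for alignment.  A probe
  ligand (7 carbon atoms) sits at the cavity center.  These fixtures probe
  the engine's geometry; they are *not* physically realistic proteins (no
  bonding, no rotamers, no realistic packing), so passing tests certify
  the descriptor definitions, not agreement with real pocket chemistry.
* **Apo/holo pairs** share the scaffold and per-site residue identities;
  the apo cavity is narrowed (radius × (1 − closure/2)) and shallowed
  (depth × (1 − closure)), so closure 0 gives an identical pair, closure 1
  a flat (ND) apo form — the bound-vs-free contrast of flexible
  interfaces.
* **Descriptor tables** emulate the bundled 12-target survey.  Draws are
  *stratified*: each variable's sample is the distribution's quantile
  midpoints (log-normal for n, clipped normal for p and the score),
  randomly paired across variables by seeded permutations.  Sample medians
  therefore equal the planted medians exactly and all recovery statistics
  are seed-independent; the seed only shuffles the joint pairing.  In
  score-consistent mode the per-structure Dscore is drawn around the
  planted median score, the pocket size drawn comonotonically with it
  (mirroring the strong size–score correlation observed across pocket
  surveys), and the enclosure solved from the score equation; where the
  solved enclosure would leave [0, 1] it is clamped and the
  hydrophilicity (in the extreme, the pocket size) re-solved so every
  realized score equals its planted value.  This is the only way to honour
  published tables whose median score is not the score of the median
  components — a skewed-sample effect; for such targets (notably the
  Bcl-xL row) the planted enclosure median deviates from the printed one
  and the manifest, not the printed table, is the recovery baseline.
  Spreads default to one sixth of the printed min–max range (≈ ±3 SD
  coverage).
* **Property tables** plant exact Lipinski-violation counts by
  largest-remainder allocation of the requested profile, drawing each
  property from disjoint compliant/violating ranges.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
slabs of ~700–2400 atoms, descriptor grids of a few thousand candidate
points, a 320-structure emulated survey, and property tables of 60–200
molecules.  The brute-force descriptor oracle runs on a reduced
configuration (margin 3 Å, ray length 6 Å) where its pure-Python loops
finish in seconds.

## Known limitations

* The descriptor engine is a surrogate: absolute n/e/p values depend on
  the stated grid, ray and contact conventions and are not interchangeable
  with any proprietary tool's output; only the score arithmetic,
  classification boundaries and aggregation conventions are anchored to
  published numbers.
* Lattice discretization makes single-structure descriptors orientation
  sensitive at the stated tolerances; median-level statistics are robust.
* Single-region assessment only: no whole-surface site scanning, no
  volume/donor-acceptor descriptors, no flexible alignment, no mmCIF.
* The survey emulation reproduces medians, spreads and classes, not the
  full joint distribution of real crystal structures.
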