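# ppidrugg

Structure-based druggability assessment and classification of
protein–protein interaction (PPI) interfaces.

PPI interfaces are notoriously flat and were long considered undruggable,
yet a growing family of targets (HDM2/p53, Bcl-2/Bax, XIAP/Smac, Menin/MLL,
…) now binds potent small-molecule inhibitors.  This package provides an
open, reproducible pipeline for asking the question a medicinal chemist
asks first: *can this interface hold a drug-like molecule?*  It is aimed at
structural bioinformaticians and computational chemists who want a
scriptable, dependency-light druggability triage for interface pockets.

## What it computes

For a binding region seeded by a (co-crystallized or superposed) ligand,
the engine detects the pocket on a 1 Å lattice and computes three
descriptors:

* **n** — the number of *site points*: lattice positions near the ligand
  that are solvent-accessible yet buried by protein;
* **e** — the *enclosure factor*: the mean fraction of 162 quasi-uniform
  ray directions blocked by protein within 10 Å, over the site points;
* **p** — the *hydrophilicity factor*: a scaled polar fraction of the
  heavy atoms lining the site (N/O, charged side-chain atoms
  double-weighted).

These feed the druggability score

```
Dscore = 0.094·√n + 0.60·e − 0.324·p
```

and a four-class PPI classification: **very druggable** (Dscore ≥ 1.0),
**druggable** (≥ 0.75), **moderately druggable** (≥ 0.5), **difficult**
(< 0.5, including interfaces where no site is detected at all — the ND
outcome typical of flat interfaces such as ZipA's).  Halgren's two-cutoff
scheme for general binding sites (< 0.8 difficult, ≥ 1.0 very druggable)
is provided for comparison.

Around the scoring core the package supplies:

* `structure_io` — PDB curation: inhibitor-bound chain selection,
  solvent/heteroatom stripping, alternate-location resolution;
* `superpose` — global sequence alignment (BLOSUM62, affine gaps) plus
  Kabsch superposition, used to transfer a reference ligand into apo or
  protein/peptide-bound structures as a pocket identifier;
* `druggability` — Dscore, both classification schemes, per-target
  aggregation (medians, sample SD, ranges, flexibility percent-reductions,
  Pearson R², pIC50);
* `druglikeness` — Lipinski Ro5, the relaxed **Ro5-1** rule (at most one
  violation), QED from the published desirability functions, and the
  Rule-of-Four profile of PPI inhibitors (Mwt > 400, ALogP > 4, HBA > 4,
  rings > 4);
* `synthetic_data` — deterministic generators for cavity/flat test
  structures, apo–holo pairs, survey-style descriptor tables and ligand
  property tables, each with a ground-truth manifest;
* `pipeline` / `ppidrugg` CLI — a manifest-driven end-to-end run
  producing survey-style report tables.

The descriptor engine is an open operationalization of the three named
quantities; it does not claim numerical identity with any proprietary
pocket-mapping tool on deposited structures (see `docs/methods.md`).

## Worked example

Score a synthetic interface pocket (radius 5 Å, depth 8 Å, 30 % polar
lining) end to end:

```python
from ppidrugg.synthetic_data import CavitySpec, make_cavity_structure
from ppidrugg.pocket_descriptors import detect_site
from ppidrugg.druggability import dscore, classify_ppi

fx = make_cavity_structure(CavitySpec(radius=5.0, depth=8.0,
                                      polar_fraction=0.3,
                                      lattice_spacing=1.5,
                                      slab_half_width=12.0,
                                      slab_thickness=13.0, seed=42))
desc = detect_site(fx.structure, fx.ligand)
print(f"n={desc.n}  e={desc.e:.2f}  p={desc.p:.2f}")
score = dscore(desc.n, desc.e, desc.p)
print(f"Dscore = {score:.2f}  ->  {classify_ppi(score)}")
```

prints

```
n=160  e=0.77  p=0.55
Dscore = 1.47  ->  very druggable
```

— a large (160 site points), well-enclosed (77 % of directions blocked),
moderately polar pocket, scoring deep in the very-druggable range.  A flat
slab (`CavitySpec(depth=0)`) instead returns the ND state and classifies
as difficult.

The same computation runs from the shell:

```bash
ppidrugg synth cavity --out fixtures --radius 5 --depth 8 --seed 42
ppidrugg descriptors --pdb fixtures/cavity.pdb --ligand LIG
ppidrugg run --config dataset/config.yaml     # full manifest-driven batch
```

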