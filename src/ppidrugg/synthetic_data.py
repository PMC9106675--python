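"""Synthetic structures, descriptor tables and ligand property tables.

Every input the pipeline consumes can be generated here, deterministically
from a spec plus a seed:

* pseudo-protein slabs with a carved cavity of controlled radius, depth,
  rim and polar lining -- the deep-pocket regime of druggable interfaces;
* flat slabs with no cavity at all -- the pocket-less regime of interfaces
  such as ZipA's, which must yield the ND outcome;
* apo/holo pairs sharing per-site residue identities, so that sequence
  alignment and superposition recover the true correspondence;
* per-target descriptor tables emulating the published survey medians,
  drawn by stratified (quantile-midpoint) sampling so that sample medians
  reproduce the planted medians exactly and recovery checks do not depend
  on the seed;
* molecular property tables with planted Lipinski-violation profiles.

Each generator also returns a manifest holding the ground truth (cavity
center, lining roster, planted medians, planted violation counts), which is
sufficient to compute every downstream expected value without running the
pipeline.

The pseudo-atoms carry real element symbols so the descriptor engine treats
fixtures exactly like deposited structures.  The slabs are not physically
realistic proteins: each lattice site is a one-atom residue with a randomly
drawn amino-acid identity (giving informative sequences), carbon by
default, nitrogen/oxygen on the polar-lining sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .druggability import DSCORE_COEFF_E, DSCORE_COEFF_N, DSCORE_COEFF_P
from .druglikeness import MoleculeProperties
from .structure_io import AtomRecord, LigandMolecule, ONE_TO_THREE, ProteinStructure

__all__ = [
    "CavitySpec",
    "CavityFixture",
    "ApoHoloPair",
    "FormSpec",
    "TargetDistributionSpec",
    "make_peptide",
    "make_cavity_structure",
    "make_apo_holo_pair",
    "make_descriptor_table",
    "make_property_table",
    "survey_emulation_specs",
    "form_emulation_specs",
]

_AA1 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Small real-backbone peptide (parsing / alignment / superposition fixtures)
# ---------------------------------------------------------------------------

def make_peptide(sequence: str = "ACDEFGHIKLMNPQRSTVWY", chain: str = "A") -> ProteinStructure:
    """An idealized helical peptide with four backbone atoms per residue.

    CA atoms trace a helix (1.5 A rise, 100 degree turn, 2.3 A radius), so
    the trace is never collinear and rigid fits are well conditioned.
    """
    atoms: list[AtomRecord] = []
    serial = 1
    for i, letter in enumerate(sequence.upper()):
        resname = ONE_TO_THREE.get(letter, "GLY")
        ang = math.radians(100.0 * i)
        ca = np.array([2.3 * math.cos(ang), 2.3 * math.sin(ang), 1.5 * i])
        offsets = {
            "N": np.array([-1.46, 0.0, -0.4]),
            "CA": np.zeros(3),
            "C": np.array([1.52, 0.0, 0.3]),
            "O": np.array([2.15, 1.05, 0.6]),
        }
        for name in ("N", "CA", "C", "O"):
            xyz = ca + offsets[name]
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_name=resname,
                    residue_seq=i + 1,
                    chain_id=chain,
                    coords=tuple(float(v) for v in xyz),
                )
            )
            serial += 1
    return ProteinStructure(atoms=atoms, id="peptide")


# ---------------------------------------------------------------------------
# Cavity slabs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CavitySpec:
    """Geometry of a pseudo-protein slab with one carved cavity.

    ``radius``/``depth`` define a flat-bottomed cylindrical well opening at
    the slab surface (depth 0 means no cavity: a flat interface).
    ``rim_height`` stacks extra atom rings around the cavity mouth.
    ``polar_fraction`` of the cavity-lining atoms are nitrogen/oxygen; the
    assignment is nested (a seeded roster prefix), so raising the fraction
    only adds polar sites.
    """

    radius: float = 4.0
    depth: float = 6.0
    polar_fraction: float = 0.0
    rim_height: float = 0.0
    lattice_spacing: float = 2.0
    slab_half_width: float | None = None
    slab_thickness: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius < 0 or self.depth < 0:
            raise ValueError("radius and depth must be >= 0")
        if not 0.0 <= self.polar_fraction <= 1.0:
            raise ValueError("polar_fraction must lie in [0, 1]")
        if self.lattice_spacing <= 0:
            raise ValueError("lattice_spacing must be positive")

    @property
    def half_width(self) -> float:
        return self.slab_half_width if self.slab_half_width is not None else self.radius + 8.0

    @property
    def thickness(self) -> float:
        return self.slab_thickness if self.slab_thickness is not None else self.depth + 6.0

    def validate_fit(self) -> None:
        if self.depth > 0 and (
            self.radius + self.lattice_spacing > self.half_width
            or self.depth + self.lattice_spacing > self.thickness
        ):
            raise ValueError("cavity larger than slab")


@dataclass
class CavityFixture:
    """A generated slab, its probe ligand and the ground-truth manifest."""

    structure: ProteinStructure
    ligand: LigandMolecule
    manifest: dict

    @property
    def complex(self) -> ProteinStructure:
        """Structure with the probe ligand included as HETATM records."""
        return ProteinStructure(
            atoms=list(self.structure.atoms) + list(self.ligand.atoms),
            id=self.structure.id + "_complex",
        )


def _lattice_sites(spec: CavitySpec) -> list[tuple[int, np.ndarray]]:
    """All slab lattice sites with stable ids, top layer first."""
    s = spec.lattice_spacing
    nxy = int(math.floor(spec.half_width / s))
    nz = int(math.floor(spec.thickness / s))
    sites = []
    sid = 0
    for iz in range(0, nz + 1):  # z = 0 (surface) down to -thickness
        for iy in range(-nxy, nxy + 1):
            for ix in range(-nxy, nxy + 1):
                sid += 1
                sites.append((sid, np.array([ix * s, iy * s, -iz * s])))
    return sites


def _rim_sites(spec: CavitySpec, start_id: int) -> list[tuple[int, np.ndarray]]:
    if spec.rim_height <= 0 or spec.depth <= 0:
        return []
    s = spec.lattice_spacing
    nxy = int(math.floor(spec.half_width / s))
    n_layers = int(math.floor(spec.rim_height / s))
    sites = []
    sid = start_id
    for iz in range(1, n_layers + 1):
        for iy in range(-nxy, nxy + 1):
            for ix in range(-nxy, nxy + 1):
                r_xy = math.hypot(ix * s, iy * s)
                if spec.radius < r_xy <= spec.radius + 1.5 * s:
                    sid += 1
                    sites.append((sid, np.array([ix * s, iy * s, iz * s])))
    return sites


def _in_void(xyz: np.ndarray, radius: float, depth: float) -> bool:
    if depth <= 0 or radius <= 0:
        return False
    return math.hypot(xyz[0], xyz[1]) < radius - 1e-9 and xyz[2] > -depth + 1e-9


def _void_distance(xyz: np.ndarray, radius: float, depth: float) -> float:
    """Distance from a point outside the void to the cylindrical void."""
    if depth <= 0 or radius <= 0:
        return math.inf
    r_xy = math.hypot(xyz[0], xyz[1])
    dr = r_xy - radius
    dz = -depth - xyz[2]
    if xyz[2] > -depth:  # beside the well
        return max(dr, 0.0)
    if r_xy < radius:  # below the well bottom
        return max(dz, 0.0)
    return math.hypot(max(dr, 0.0), max(dz, 0.0))


def _site_residues(spec: CavitySpec, n_sites: int) -> list[str]:
    """Per-site amino-acid identities; a pure function of seed and count."""
    rng = np.random.default_rng([int(spec.seed) % (2**31), 101])
    letters = rng.integers(0, len(_AA1), size=n_sites)
    return [ONE_TO_THREE[_AA1[i]] for i in letters]


def _build_cavity(
    spec: CavitySpec,
    carve_radius: float,
    carve_depth: float,
    polar_map: dict[int, str] | None,
    structure_id: str,
) -> CavityFixture:
    spec.validate_fit()
    slab_sites = _lattice_sites(spec)
    rim = _rim_sites(spec, start_id=len(slab_sites))
    resnames = _site_residues(spec, len(slab_sites) + len(rim))

    kept = [(sid, xyz) for sid, xyz in slab_sites if not _in_void(xyz, carve_radius, carve_depth)]
    kept += rim

    if polar_map is None:
        # lining roster of *this* cavity, in a seeded nested order
        shell = spec.lattice_spacing + 0.1
        lining = [
            sid
            for sid, xyz in kept
            if _void_distance(xyz, carve_radius, carve_depth) <= shell
        ]
        rng = np.random.default_rng([int(spec.seed) % (2**31), 202])
        roster = [lining[i] for i in rng.permutation(len(lining))]
        n_polar = int(round(spec.polar_fraction * len(roster)))
        polar_map = {
            sid: ("N" if k % 2 == 0 else "O") for k, sid in enumerate(roster[:n_polar])
        }

    atoms: list[AtomRecord] = []
    for serial, (sid, xyz) in enumerate(kept, start=1):
        element = polar_map.get(sid, "C")
        atoms.append(
            AtomRecord(
                serial=serial,
                name={"C": "CA", "N": "N", "O": "O"}[element],
                element=element,
                residue_name=resnames[sid - 1],
                residue_seq=sid,
                chain_id="A",
                coords=tuple(float(v) for v in xyz),
            )
        )
    structure = ProteinStructure(atoms=atoms, id=structure_id)

    center = (
        np.array([0.0, 0.0, -carve_depth / 2.0])
        if carve_depth > 0
        else np.array([0.0, 0.0, 2.0])
    )
    lig_atoms = []
    offsets = [
        (0.0, 0.0, 0.0),
        (1.2, 0.0, 0.0), (-1.2, 0.0, 0.0),
        (0.0, 1.2, 0.0), (0.0, -1.2, 0.0),
        (0.0, 0.0, 1.2), (0.0, 0.0, -1.2),
    ]
    for k, off in enumerate(offsets, start=1):
        lig_atoms.append(
            AtomRecord(
                serial=len(atoms) + k,
                name=f"C{k}",
                element="C",
                residue_name="LIG",
                residue_seq=9999,
                chain_id="A",
                coords=tuple(float(v) for v in center + np.array(off)),
                is_hetero=True,
            )
        )
    ligand = LigandMolecule(atoms=lig_atoms, residue_name="LIG")

    manifest = {
        "cavity_center": [float(v) for v in center],
        "carve_radius": carve_radius,
        "carve_depth": carve_depth,
        "n_atoms": len(atoms),
        "n_rim_atoms": len(rim),
        "polar_serials": sorted(
            a.serial for a in atoms if a.element in ("N", "O")
        ),
        "lining_serials": sorted(
            a.serial
            for a in atoms
            if _void_distance(np.array(a.coords), carve_radius, carve_depth)
            <= spec.lattice_spacing + 0.1
        ),
        "spec": {
            "radius": spec.radius,
            "depth": spec.depth,
            "polar_fraction": spec.polar_fraction,
            "rim_height": spec.rim_height,
            "lattice_spacing": spec.lattice_spacing,
            "seed": spec.seed,
        },
    }
    return CavityFixture(structure=structure, ligand=ligand, manifest=manifest)


def make_cavity_structure(spec: CavitySpec) -> CavityFixture:
    """Slab with the spec's cavity carved out and a probe ligand inside."""
    return _build_cavity(spec, spec.radius, spec.depth, None, "cavity")


@dataclass
class ApoHoloPair:
    apo: CavityFixture
    holo: CavityFixture
    closure: float


def make_apo_holo_pair(spec: CavitySpec, closure: float) -> ApoHoloPair:
    """An apo/holo pair of the same scaffold.

    The holo form carries the full cavity; the apo form's cavity is
    narrowed and shallowed with the closure fraction -- depth scales with
    (1 - closure) and radius with (1 - closure/2), so intermediate closures
    keep a smaller but detectable pocket while closure 1 restores a flat
    slab (ND) and closure 0 leaves the pair identical.  Shared lattice
    sites keep the
    same residue identity and element in both forms, so sequence alignment
    recovers the true correspondence.  The probe ligand belongs to the holo
    form only.
    """
    if not 0.0 <= closure <= 1.0:
        raise ValueError("closure must lie in [0, 1]")
    holo = make_cavity_structure(spec)
    polar_map = {
        a.residue_seq: a.element
        for a in holo.structure.atoms
        if a.element in ("N", "O")
    }
    apo = _build_cavity(
        spec,
        spec.radius * (1.0 - closure / 2.0),
        spec.depth * (1.0 - closure),
        polar_map,
        "apo",
    )
    return ApoHoloPair(apo=apo, holo=holo, closure=closure)


# ---------------------------------------------------------------------------
# Descriptor tables emulating the published survey
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FormSpec:
    """Distribution of (n, e, p) for one crystal form of one target.

    When ``dscore_median`` is set the enclosure draw is derived from the
    score equation (score-consistent mode): a Dscore value is drawn around
    the planted median and ``e`` solved from it given the drawn ``n`` and
    ``p``.  This reproduces surveys whose reported median score is not the
    score of the reported component medians (a skewed-sample effect);
    otherwise ``e`` is drawn independently around ``e_median``.
    """

    form: str
    count: int
    n_median: float = 0.0
    p_median: float = 0.0
    e_median: float | None = None
    dscore_median: float | None = None
    n_log_spread: float = 0.25
    e_spread: float = 0.05
    p_spread: float = 0.05
    dscore_spread: float = 0.08
    detected: bool = True

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.detected and self.e_median is None and self.dscore_median is None:
            raise ValueError("need e_median or dscore_median")


@dataclass(frozen=True)
class TargetDistributionSpec:
    target: str
    forms: tuple[FormSpec, ...]
    seed: int = 0


def _stratified_z(m: int) -> np.ndarray:
    """Midpoint quantiles of the standard normal: the sample median equals
    the distribution median exactly, for odd and (by symmetry) even m."""
    return norm.ppf((np.arange(m) + 0.5) / m)


def make_descriptor_table(
    spec: TargetDistributionSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a per-structure descriptor table and its ground-truth manifest.

    Marginals are stratified: each variable's draws are the distribution's
    quantile midpoints, randomly paired across variables by seeded
    permutations.  Spread 0 collapses every draw onto the median.
    """
    rng = np.random.default_rng([int(spec.seed) % (2**31), 303])
    rows = []
    truth = []
    for fs in spec.forms:
        m = fs.count
        z = _stratified_z(m)
        if not fs.detected:
            for i in range(m):
                sid = f"{spec.target}-{fs.form}-{i + 1:03d}".replace(" ", "_")
                rows.append((sid, spec.target, fs.form, False, np.nan, np.nan, np.nan))
                truth.append((sid, fs.form, np.nan, np.nan, np.nan, np.nan))
            continue
        z_n = z[rng.permutation(m)]
        z_p = z[rng.permutation(m)]
        n_draw = np.maximum(1, np.rint(fs.n_median * np.exp(fs.n_log_spread * z_n))).astype(int)
        p_draw = np.maximum(0.0, fs.p_median + fs.p_spread * z_p)
        if fs.dscore_median is not None:
            # pocket size and score are drawn comonotonically, mirroring the
            # strong positive size-score correlation seen in pocket surveys;
            # this also keeps the solved enclosure inside [0, 1]
            z_d = z_n
            d_draw = np.maximum(0.01, fs.dscore_median + fs.dscore_spread * z_d)
            e_draw = (d_draw + DSCORE_COEFF_P * p_draw - DSCORE_COEFF_N * np.sqrt(n_draw)) / DSCORE_COEFF_E
            # keep each realized score equal to its planted value: where the
            # solved enclosure leaves [0, 1], clamp it and re-solve the
            # hydrophilicity (and, in the extreme, the pocket size)
            for i in range(m):
                if e_draw[i] > 1.0:
                    e_draw[i] = 1.0
                    p_draw[i] = (
                        DSCORE_COEFF_N * math.sqrt(n_draw[i]) + DSCORE_COEFF_E - d_draw[i]
                    ) / DSCORE_COEFF_P
                    if p_draw[i] < 0.0:
                        p_draw[i] = 0.0
                        n_draw[i] = int(
                            math.ceil(((d_draw[i] - DSCORE_COEFF_E) / DSCORE_COEFF_N) ** 2)
                        )
                elif e_draw[i] < 0.0:
                    e_draw[i] = 0.0
                    p_draw[i] = (
                        DSCORE_COEFF_N * math.sqrt(n_draw[i]) - d_draw[i]
                    ) / DSCORE_COEFF_P
        else:
            z_e = z[rng.permutation(m)]
            e_draw = np.clip(fs.e_median + fs.e_spread * z_e, 0.0, 1.0)
        realized = (
            DSCORE_COEFF_N * np.sqrt(n_draw)
            + DSCORE_COEFF_E * e_draw
            - DSCORE_COEFF_P * p_draw
        )
        for i in range(m):
            sid = f"{spec.target}-{fs.form}-{i + 1:03d}".replace(" ", "_")
            rows.append(
                (sid, spec.target, fs.form, True, n_draw[i], float(e_draw[i]), float(p_draw[i]))
            )
            truth.append((sid, fs.form, n_draw[i], float(e_draw[i]), float(p_draw[i]), float(realized[i])))
    table = pd.DataFrame(
        rows, columns=["structure_id", "target", "form", "detected", "n", "e", "p"]
    )
    manifest = pd.DataFrame(
        truth, columns=["structure_id", "form", "n", "e", "p", "dscore"]
    )
    return table, manifest


def survey_emulation_specs(seed: int = 0) -> list[TargetDistributionSpec]:
    """Specs emulating the 12-target survey from the published per-target
    medians (pooled over crystal forms; the flat-interface target is all
    ND).  Spreads are set to one sixth of each printed min-max range."""
    from . import reference

    specs = []
    for target, row in reference.TARGET_MEDIANS.items():
        if row["dscore"] is None:
            fs = FormSpec(form="ligand_bound", count=row["count"], detected=False)
        else:
            n_lo, n_hi = row["n_range"]
            d_lo, d_hi = row["dscore_range"]
            p_lo, p_hi = row["p_range"]
            fs = FormSpec(
                form="ligand_bound",
                count=row["count"],
                n_median=row["n"],
                p_median=row["p"],
                dscore_median=row["dscore"],
                n_log_spread=math.log(n_hi / n_lo) / 6.0,
                dscore_spread=(d_hi - d_lo) / 6.0,
                p_spread=(p_hi - p_lo) / 6.0,
            )
        specs.append(TargetDistributionSpec(target=target, forms=(fs,), seed=seed))
    return specs


def form_emulation_specs(seed: int = 0) -> list[TargetDistributionSpec]:
    """Specs emulating the per-crystal-form breakdown (apo vs protein/
    peptide-bound vs ligand-bound medians) of the published survey."""
    from . import reference

    specs = []
    for target, forms in reference.FORM_MEDIANS.items():
        fss = []
        for form, row in forms.items():
            if row["dscore"] is None:
                fss.append(FormSpec(form=form, count=row["count"], detected=False))
                continue
            n_med = row["n"]
            n_sd = row["n_sd"] or 0.0
            fss.append(
                FormSpec(
                    form=form,
                    count=row["count"],
                    n_median=n_med,
                    p_median=reference.TARGET_MEDIANS[target]["p"] or 0.0,
                    dscore_median=row["dscore"],
                    dscore_spread=row["dscore_sd"] or 0.0,
                    n_log_spread=(n_sd / n_med) if n_med else 0.0,
                    p_spread=0.05,
                )
            )
        specs.append(TargetDistributionSpec(target=target, forms=tuple(fss), seed=seed))
    return specs


# ---------------------------------------------------------------------------
# Ligand property tables with planted Lipinski-violation profiles
# ---------------------------------------------------------------------------

_COMPLIANT = {
    "mwt": (250.0, 480.0),
    "logp": (0.5, 4.5),
    "hbd": (0, 5),
    "hba": (1, 9),
}
_VIOLATING = {
    "mwt": (520.0, 900.0),
    "logp": (5.3, 8.5),
    "hbd": (6, 9),
    "hba": (11, 15),
}
_RULES = ("mwt", "logp", "hbd", "hba")


def make_property_table(
    n_mol: int,
    violation_profile: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[list[MoleculeProperties], pd.DataFrame]:
    """Molecules with planted numbers of Lipinski violations.

    ``violation_profile`` maps a violation count (1-4) to the fraction of
    molecules carrying exactly that many violations; the remainder are
    fully compliant.  Counts are allocated by largest remainder so they sum
    to ``n_mol`` exactly, and the manifest records the planted count per
    molecule.
    """
    violation_profile = violation_profile or {}
    if any(not 1 <= k <= 4 for k in violation_profile):
        raise ValueError("violation counts must be 1-4")
    if any(f < 0 for f in violation_profile.values()) or sum(violation_profile.values()) > 1 + 1e-9:
        raise ValueError("fractions must be >= 0 and sum to <= 1")
    rng = np.random.default_rng([int(seed) % (2**31), 404])

    quotas = {k: n_mol * f for k, f in sorted(violation_profile.items())}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    deficit = int(round(sum(quotas.values()))) - sum(counts.values())
    by_remainder = sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in by_remainder[: max(deficit, 0)]:
        counts[k] += 1
    plan = []
    for k, c in counts.items():
        plan += [k] * c
    plan += [0] * (n_mol - len(plan))

    molecules = []
    truth = []
    for i, n_viol in enumerate(plan, start=1):
        broken = set(rng.choice(len(_RULES), size=n_viol, replace=False).tolist())
        vals: dict[str, float] = {}
        for j, rule in enumerate(_RULES):
            lo, hi = (_VIOLATING if j in broken else _COMPLIANT)[rule]
            if rule in ("hbd", "hba"):
                vals[rule] = int(rng.integers(lo, hi + 1))
            else:
                vals[rule] = float(np.round(rng.uniform(lo, hi), 2))
        mol = MoleculeProperties(
            id=f"M{i:04d}",
            mwt=vals["mwt"],
            hbd=vals["hbd"],
            hba=vals["hba"],
            logp=vals["logp"],
            psa=float(np.round(rng.uniform(50.0, 120.0), 1)),
            rotb=int(rng.integers(2, 11)),
            arom_rings=int(rng.integers(1, 5)),
            alerts=int(rng.integers(0, 5) == 0),
        )
        molecules.append(mol)
        truth.append(
            {
                "id": mol.id,
                "planted_violations": n_viol,
                "violated_rules": ",".join(_RULES[j] for j in sorted(broken)),
            }
        )
    return molecules, pd.DataFrame(truth)
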