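"""Grid-based pocket descriptors: site points, enclosure, hydrophilicity.

This module is an open operationalization of the three quantities entering
the druggability score Dscore = 0.094*sqrt(n) + 0.60*e - 0.324*p:

``n``
    the number of *site points* -- lattice positions near the seeding ligand
    that are solvent-accessible yet sufficiently buried by protein;
``e``
    the *enclosure factor* -- the mean fraction of quasi-uniform ray
    directions along which a protein heavy atom blocks the view from a site
    point within a fixed horizon;
``p``
    the *hydrophilicity factor* -- a scaled polar fraction of the protein
    heavy atoms lining the site (nitrogen/oxygen count; charged side-chain
    N/O are double-weighted), mapped onto the empirically observed range of
    SiteMap's philic score by the calibration constant ``k_p``.

Flat interfaces with no buried lattice component larger than
``min_site_points`` yield the ND (no site detected) outcome, mirroring the
behaviour of druggability tools on pocket-less interfaces such as ZipA's.

Everything is deterministic: the ray set is a fixed icosphere, the lattice
is anchored at the ligand centroid (so descriptors are exactly invariant
under rigid translations of the complex and do not depend on the deposition
frame), and no randomness enters anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure_io import LigandMolecule, ProteinStructure

__all__ = [
    "BONDI_RADII",
    "PocketConfig",
    "SiteDescriptors",
    "icosphere_directions",
    "vdw_radius",
    "candidate_grid",
    "enclosure_at",
    "detect_site",
]

#: Bondi (1964) van der Waals radii in Angstrom; heavy atoms only are used.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "B": 1.92, "SI": 2.10, "ZN": 1.39, "MG": 1.73,
}
_DEFAULT_RADIUS = 1.70

#: Charged side-chain nitrogen/oxygen atoms (double-weighted in ``p``).
CHARGED_POLAR_ATOMS: frozenset[tuple[str, str]] = frozenset(
    {
        ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
        ("LYS", "NZ"),
        ("ASP", "OD1"), ("ASP", "OD2"),
        ("GLU", "OE1"), ("GLU", "OE2"),
    }
)


def vdw_radius(element: str) -> float:
    return BONDI_RADII.get(element.upper(), _DEFAULT_RADIUS)


def icosphere_directions(subdivisions: int = 2) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors from a subdivided icosahedron.

    ``subdivisions=2`` yields the default 162 directions (10*4^k + 2
    vertices).  The vertex order is fixed by lexicographic sorting of the
    rounded coordinates, making the ray set bit-reproducible.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = [
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    v = [np.array(x, dtype=float) / np.linalg.norm(x) for x in verts]

    def midpoint(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        m = (a + b) / 2.0
        return m / np.linalg.norm(m)

    for _ in range(subdivisions):
        new_faces = []
        for ia, ib, ic in faces:
            a, b, c = v[ia], v[ib], v[ic]
            for m in (midpoint(a, b), midpoint(b, c), midpoint(c, a)):
                v.append(m)
            n = len(v)
            iab, ibc, ica = n - 3, n - 2, n - 1
            new_faces += [
                (ia, iab, ica), (ib, ibc, iab), (ic, ica, ibc), (iab, ibc, ica)
            ]
        faces = new_faces
    # dedupe shared edge midpoints; unique() also fixes a lexicographic order
    arr = np.unique(np.round(np.array(v), 9), axis=0)
    return arr / np.linalg.norm(arr, axis=1, keepdims=True)


@dataclass(frozen=True)
class PocketConfig:
    """Tunable parameters of the descriptor engine (lengths in Angstrom)."""

    grid_spacing: float = 1.0
    region_margin: float = 6.0
    probe_radius: float = 1.4
    ray_subdivisions: int = 2  # 162 directions
    ray_length: float = 10.0
    enclosure_threshold: float = 0.5
    min_site_points: int = 5
    contact_cutoff: float = 4.0
    hydrophilicity_scale: float = 1.6  # k_p

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if not 0.0 < self.enclosure_threshold < 1.0:
            raise ValueError("enclosure_threshold must be in (0, 1)")

    @property
    def ray_count(self) -> int:
        return 10 * 4**self.ray_subdivisions + 2

    def directions(self) -> np.ndarray:
        return icosphere_directions(self.ray_subdivisions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PocketConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class SiteDescriptors:
    """The three Dscore ingredients, or the ND (no site detected) state."""

    n: int | None
    e: float | None
    p: float | None
    detected: bool

    def __post_init__(self) -> None:
        if self.detected:
            if self.n is None or self.e is None or self.p is None:
                raise ValueError("detected site must carry n, e and p")
            if not 0.0 <= self.e <= 1.0:
                raise ValueError("enclosure factor must lie in [0, 1]")
            if self.p < 0:
                raise ValueError("hydrophilicity factor must be >= 0")
        elif (self.n, self.e, self.p) != (None, None, None):
            raise ValueError("ND state carries no descriptor values")

    @classmethod
    def nd(cls) -> "SiteDescriptors":
        return cls(n=None, e=None, p=None, detected=False)


def _protein_arrays(structure: ProteinStructure):
    atoms = structure.protein_atoms()
    coords = np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)
    radii = np.array([vdw_radius(a.element) for a in atoms], dtype=float)
    return atoms, coords, radii


def _grid_points(ligand: LigandMolecule, config: PocketConfig):
    """Lattice anchored at the ligand centroid covering its bounding box
    expanded by the region margin; returns (points, integer indices)."""
    anchor = ligand.centroid
    rel = ligand.coordinates() - anchor
    lo = np.floor((rel.min(axis=0) - config.region_margin) / config.grid_spacing).astype(int)
    hi = np.ceil((rel.max(axis=0) + config.region_margin) / config.grid_spacing).astype(int)
    axes = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    ijk = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    points = anchor + ijk * config.grid_spacing
    return points, ijk


def candidate_grid(
    structure: ProteinStructure,
    ligand: LigandMolecule,
    config: PocketConfig | None = None,
) -> np.ndarray:
    """Candidate site points: the ligand-region lattice minus every point
    lying within vdW radius + probe radius of a protein heavy atom."""
    config = config or PocketConfig()
    points, _ = _candidate_grid_indexed(structure, ligand, config)
    return points


def _candidate_grid_indexed(structure, ligand, config):
    points, ijk = _grid_points(ligand, config)
    _, coords, radii = _protein_arrays(structure)
    if coords.shape[0] == 0:
        return points, ijk
    tree = cKDTree(points)
    clash = np.zeros(len(points), dtype=bool)
    for xyz, r in zip(coords, radii):
        for idx in tree.query_ball_point(xyz, r + config.probe_radius):
            clash[idx] = True
    return points[~clash], ijk[~clash]


def _enclosure_batch(
    points: np.ndarray,
    coords: np.ndarray,
    radii: np.ndarray,
    config: PocketConfig,
) -> np.ndarray:
    """Fraction of fixed ray directions blocked within the ray horizon,
    for each query point (exact ray/sphere intersection tests)."""
    dirs = config.directions()
    n_pts = len(points)
    out = np.zeros(n_pts)
    if coords.shape[0] == 0 or n_pts == 0:
        return out
    tree = cKDTree(coords)
    reach = config.ray_length + radii.max()
    neighborhoods = tree.query_ball_point(points, reach)
    for i, neigh in enumerate(neighborhoods):
        if not neigh:
            continue
        v = coords[neigh] - points[i]  # (k, 3)
        r = radii[neigh]
        t = v @ dirs.T  # (k, d) distance along each ray to closest approach
        b2 = (v**2).sum(axis=1)[:, None] - t**2  # squared perp distance
        disc = r[:, None] ** 2 - b2
        hit = disc >= 0.0
        np.logical_and(hit, t >= 0.0, out=hit)
        t_entry = t - np.sqrt(np.clip(disc, 0.0, None))
        np.logical_and(hit, t_entry <= config.ray_length, out=hit)
        out[i] = hit.any(axis=0).mean()
    return out


def enclosure_at(
    point: np.ndarray,
    structure: ProteinStructure,
    config: PocketConfig | None = None,
) -> float:
    """Enclosure fraction at one point (ray casting against vdW spheres)."""
    config = config or PocketConfig()
    _, coords, radii = _protein_arrays(structure)
    return float(
        _enclosure_batch(np.asarray(point, dtype=float).reshape(1, 3), coords, radii, config)[0]
    )


def _pick_component(labels, ijk, points, centroid, min_size):
    """The connected component closest to the ligand centroid; ties broken
    by larger size, then lexicographic grid order."""
    best = None
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        size = int(mask.sum())
        dist = float(np.linalg.norm(points[mask] - centroid, axis=1).min())
        first = tuple(int(x) for x in ijk[mask][np.lexsort(ijk[mask].T[::-1])][0])
        key = (round(dist, 9), -size, first)
        if best is None or key < best[0]:
            best = (key, mask)
    return best[1] if best is not None else None


def detect_site(
    structure: ProteinStructure,
    ligand: LigandMolecule,
    config: PocketConfig | None = None,
) -> SiteDescriptors:
    """Detect the single ligand-seeded binding site and compute (n, e, p).

    Site points are candidate grid points with enclosure at or above the
    threshold, clustered by 26-neighbour grid connectivity; the component
    closest to the ligand centroid is the site.  Returns the ND state when
    the chosen component has fewer than ``min_site_points`` points (flat,
    pocket-less interfaces).
    """
    config = config or PocketConfig()
    atoms, coords, radii = _protein_arrays(structure)
    points, ijk = _candidate_grid_indexed(structure, ligand, config)
    if len(points) == 0:
        return SiteDescriptors.nd()
    encl = _enclosure_batch(points, coords, radii, config)
    buried = encl >= config.enclosure_threshold
    if not buried.any():
        return SiteDescriptors.nd()
    ijk_b = ijk[buried]
    pts_b = points[buried]
    encl_b = encl[buried]
    lo = ijk_b.min(axis=0)
    shape = ijk_b.max(axis=0) - lo + 1
    vol = np.zeros(shape, dtype=bool)
    vol[tuple((ijk_b - lo).T)] = True
    labels_vol, _ = ndimage.label(vol, structure=np.ones((3, 3, 3), dtype=int))
    labels = labels_vol[tuple((ijk_b - lo).T)]
    mask = _pick_component(labels, ijk_b, pts_b, ligand.centroid, config.min_site_points)
    if mask is None or int(mask.sum()) < config.min_site_points:
        return SiteDescriptors.nd()
    site_points = pts_b[mask]
    n = int(mask.sum())
    e = float(encl_b[mask].mean())
    # hydrophilicity: polar-weighted fraction of lining heavy atoms
    site_tree = cKDTree(site_points)
    d, _ = site_tree.query(coords, k=1)
    contact = d <= config.contact_cutoff
    total = int(contact.sum())
    if total == 0:
        p = 0.0
    else:
        weight = 0.0
        for atom in (a for a, c in zip(atoms, contact) if c):
            elem = atom.element.upper()
            if elem in ("N", "O"):
                w = 1.0
                if (atom.residue_name.upper(), atom.name.upper()) in CHARGED_POLAR_ATOMS:
                    w = 2.0
                weight += w
        p = config.hydrophilicity_scale * weight / total
    return SiteDescriptors(n=n, e=min(e, 1.0), p=p, detected=True)
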