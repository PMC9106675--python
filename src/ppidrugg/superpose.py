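"""Sequence alignment and rigid-body superposition.

Apo and protein/peptide-bound structures carry no pocket-seeding ligand, so
each is paired with a ligand-bound reference: the two sequences are globally
aligned, the C-alpha atoms of aligned residue pairs are fitted by the Kabsch
algorithm, and the *inverse* transform is applied to the reference ligand so
that the target structure keeps its native coordinate frame while gaining a
posed pocket identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import LigandMolecule, ProteinStructure

__all__ = [
    "AlignmentMap",
    "RigidTransform",
    "AlignmentError",
    "DegenerateFitError",
    "InsufficientOverlapError",
    "global_align",
    "kabsch",
    "superpose_on_reference",
    "transform_structure",
]


class AlignmentError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


class InsufficientOverlapError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentMap:
    """Global alignment as ordered, strictly increasing residue index pairs.

    Indices are 0-based positions into the two input sequences.
    """

    pairs: tuple[tuple[int, int], ...]
    score: float

    def __post_init__(self) -> None:
        for (a0, b0), (a1, b1) in zip(self.pairs, self.pairs[1:]):
            if a1 <= a0 or b1 <= b0:
                raise AlignmentError("alignment pairs must be strictly increasing")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation, with the RMSD of
    the least-squares fit it came from."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise DegenerateFitError("rotation must be 3x3 orthonormal")
        if np.linalg.det(r) < 0:
            raise DegenerateFitError("rotation must be proper (det=+1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation, self.rmsd)


def _substitution_matrix(name: str):
    m = substitution_matrices.load(name)
    arr = np.array(m)
    alphabet = m.alphabet
    if "X" in alphabet:  # unknown residues contribute nothing to the score
        i = alphabet.index("X")
        arr[i, :] = 0.0
        arr[:, i] = 0.0
    out = substitution_matrices.Array(alphabet=alphabet, dims=2, data=arr)
    return out


def global_align(
    seq_a: str,
    seq_b: str,
    substitution: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> AlignmentMap:
    """Optimal global alignment under affine gap penalties.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  Unknown
    residues (``X``) are allowed and score zero against everything.  Ties
    between co-optimal alignments are broken deterministically (first
    alignment in the aligner's canonical enumeration order).
    """
    if not seq_a or not seq_b:
        raise AlignmentError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _substitution_matrix(substitution)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    alignments = aligner.align(seq_a.upper(), seq_b.upper())
    best = alignments[0]
    pairs: list[tuple[int, int]] = []
    blocks_a, blocks_b = best.aligned
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        pairs.extend((a0 + k, b0 + k) for k in range(a1 - a0))
    return AlignmentMap(pairs=tuple(pairs), score=float(alignments.score))


def kabsch(p: np.ndarray, q: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of point set ``p`` onto ``q``.

    Returns the proper rotation and translation minimizing the RMSD between
    the transformed ``p`` and ``q``; reflections are corrected by the usual
    sign flip of the smallest singular vector.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise DegenerateFitError("point sets must both be N x 3")
    n = p.shape[0]
    if n < 3:
        raise DegenerateFitError("need at least 3 paired points")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    sv = np.linalg.svd(pc, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateFitError("points are collinear; rotation undetermined")
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    t = q.mean(axis=0) - rot @ p.mean(axis=0)
    resid = p @ rot.T + t - q
    rmsd = float(np.sqrt((resid**2).sum() / n))
    return RigidTransform(rotation=rot, translation=t, rmsd=rmsd)


def transform_structure(
    structure: ProteinStructure, transform: RigidTransform
) -> ProteinStructure:
    """Apply a rigid motion to every atom, returning a new structure."""
    new_atoms = []
    for a in structure.atoms:
        xyz = transform.apply(np.asarray(a.coords))
        new_atoms.append(replace(a, coords=tuple(float(v) for v in xyz)))
    return ProteinStructure(atoms=new_atoms, id=structure.id)


def _sequence_residues(structure: ProteinStructure) -> list[dict]:
    """Residues in the exact order used by ``ProteinStructure.sequence``."""
    from .structure_io import is_protein_residue

    out = []
    for res in structure.residues():
        if is_protein_residue(res["name"]):
            out.append(res)
        elif not any(a.is_hetero for a in res["atoms"].values()):
            out.append(res)
    return out


def _ca_pairs(
    target: ProteinStructure, reference: ProteinStructure, alignment: AlignmentMap
) -> tuple[np.ndarray, np.ndarray]:
    res_t = _sequence_residues(target)
    res_r = _sequence_residues(reference)
    pts_t, pts_r = [], []
    for i, j in alignment.pairs:
        at = res_t[i]["atoms"].get("CA")
        ar = res_r[j]["atoms"].get("CA")
        if at is not None and ar is not None:
            pts_t.append(at.coords)
            pts_r.append(ar.coords)
    return np.array(pts_t, dtype=float), np.array(pts_r, dtype=float)


def superpose_on_reference(
    target: ProteinStructure,
    reference: ProteinStructure,
    reference_ligand: LigandMolecule,
    min_pairs: int = 20,
    trim_outliers: bool = False,
    max_trim_rounds: int = 3,
    **align_kwargs,
) -> tuple[ProteinStructure, LigandMolecule, RigidTransform]:
    """Pose the reference ligand into the (unmoved) target structure.

    The target and reference sequences are globally aligned, aligned-pair
    C-alpha atoms are fitted with :func:`kabsch` (target onto reference),
    and the inverse transform carries the reference ligand into the target
    frame.  Optional iterative trimming drops pairs deviating by more than
    two standard deviations, up to ``max_trim_rounds`` rounds, never below
    ``min_pairs`` pairs.
    """
    alignment = global_align(target.sequence(), reference.sequence(), **align_kwargs)
    pts_t, pts_r = _ca_pairs(target, reference, alignment)
    if len(pts_t) < min_pairs:
        raise InsufficientOverlapError(
            f"only {len(pts_t)} aligned C-alpha pairs; need >= {min_pairs}"
        )
    fit = kabsch(pts_t, pts_r)
    if trim_outliers:
        for _ in range(max_trim_rounds):
            dev = np.linalg.norm(pts_t @ fit.rotation.T + fit.translation - pts_r, axis=1)
            keep = dev <= dev.mean() + 2.0 * dev.std()
            if keep.sum() < min_pairs or keep.all():
                break
            pts_t, pts_r = pts_t[keep], pts_r[keep]
            fit = kabsch(pts_t, pts_r)
    posed = reference_ligand.transformed(
        fit.inverse().rotation, fit.inverse().translation
    )
    return target, posed, fit
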