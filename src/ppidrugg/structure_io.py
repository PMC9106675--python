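"""Reading, curating and writing protein/ligand structures.

Implements the curation rules used throughout the pipeline: only the chain
bound to the inhibitor is retained, solvent and co-crystallized heteroatoms
are stripped (except an explicitly kept ligand), alternate locations are
resolved to the highest-occupancy conformer, and hydrogens are ignored
(all downstream descriptors are heavy-atom based).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ProteinStructure",
    "LigandMolecule",
    "StructureError",
    "EmptyStructureError",
    "NoBoundChainError",
    "MissingLigandError",
    "AmbiguousLigandError",
    "read_pdb",
    "write_pdb",
    "select_chain",
    "strip_non_protein",
    "extract_ligand",
]


class StructureError(ValueError):
    """Base class for structure curation failures."""


class EmptyStructureError(StructureError):
    """Raised when no usable atoms remain after parsing or curation."""


class NoBoundChainError(StructureError):
    """Raised when no chain lies within the contact cutoff of the ligand."""


class MissingLigandError(StructureError):
    """Raised when a named ligand residue is absent from the structure."""


class AmbiguousLigandError(StructureError):
    """Raised when a ligand residue name matches several copies and no
    chain disambiguation is given."""


#: Three-letter -> one-letter codes for the 20 standard amino acids plus the
#: common modified residues retained as protein during curation.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues kept as protein (mapped to their parent)
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y",
}

WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O", "TIP", "SOL"}

ONE_TO_THREE = {v: k for k, v in reversed(list(THREE_TO_ONE.items()))}


def is_protein_residue(residue_name: str) -> bool:
    return residue_name.upper() in THREE_TO_ONE


def is_water(residue_name: str) -> bool:
    return residue_name.upper() in WATER_RESIDUES


@dataclass(frozen=True)
class AtomRecord:
    """A single heavy-atom (or hydrogen) record in deposition order."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: tuple[float, float, float]
    is_hetero: bool = False
    icode: str = ""
    occupancy: float = 1.0

    @property
    def residue_id(self) -> tuple[str, int, str, str]:
        """Identity of the residue this atom belongs to (chain, seq, icode,
        name); insertion codes are preserved to avoid residue collisions."""
        return (self.chain_id, self.residue_seq, self.icode, self.residue_name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class ProteinStructure:
    """Flat, ordered heavy-atom model of one crystal structure."""

    atoms: list[AtomRecord]
    id: str = ""

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def coordinates(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        if not atoms:
            return np.empty((0, 3))
        return np.array([a.coords for a in atoms], dtype=float)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def protein_atoms(self) -> list[AtomRecord]:
        return [a for a in self.heavy_atoms() if is_protein_residue(a.residue_name)]

    def residues(self, chain: str | None = None) -> list[dict]:
        """Ordered residues as dicts with keys chain, seq, icode, name and an
        ``atoms`` mapping of atom name -> AtomRecord (first occurrence wins)."""
        out: list[dict] = []
        index: dict[tuple, int] = {}
        for a in self.atoms:
            if chain is not None and a.chain_id != chain:
                continue
            key = a.residue_id
            if key not in index:
                index[key] = len(out)
                out.append(
                    {
                        "chain": a.chain_id,
                        "seq": a.residue_seq,
                        "icode": a.icode,
                        "name": a.residue_name,
                        "atoms": {},
                    }
                )
            out[index[key]]["atoms"].setdefault(a.name, a)
        return out

    def sequence(self, chain: str | None = None) -> str:
        """One-letter amino-acid sequence derived from the residue records.

        Non-protein residues are skipped; unknown protein-like residues in
        ATOM records are emitted as ``X``.
        """
        letters = []
        for res in self.residues(chain):
            name = res["name"].upper()
            if is_protein_residue(name):
                letters.append(THREE_TO_ONE[name])
            elif not any(a.is_hetero for a in res["atoms"].values()):
                letters.append("X")
        return "".join(letters)

    def subset(self, atoms: list[AtomRecord], id_suffix: str = "") -> "ProteinStructure":
        return ProteinStructure(atoms=list(atoms), id=self.id + id_suffix)


@dataclass
class LigandMolecule:
    """Heavy atoms of a small molecule used to seed pocket detection."""

    atoms: list[AtomRecord]
    residue_name: str

    def __post_init__(self) -> None:
        self.atoms = [a for a in self.atoms if not a.is_hydrogen]
        if not self.atoms:
            raise MissingLigandError(
                f"ligand {self.residue_name!r} has no heavy atoms"
            )

    def coordinates(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def centroid(self) -> np.ndarray:
        return self.coordinates().mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandMolecule":
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_atoms = []
        for a in self.atoms:
            xyz = rotation @ np.asarray(a.coords) + translation
            new_atoms.append(replace(a, coords=tuple(float(v) for v in xyz)))
        return LigandMolecule(new_atoms, self.residue_name)


# ---------------------------------------------------------------------------
# PDB input / output (gemmi backend)
# ---------------------------------------------------------------------------

def _resolve_altlocs(raw: list[tuple[str, float, AtomRecord]]) -> list[AtomRecord]:
    """Keep one conformer per (residue, atom name): the highest occupancy,
    ties broken by first-listed order."""
    best: dict[tuple, tuple[float, int, AtomRecord]] = {}
    order: list[tuple] = []
    for listed, (altloc, occ, atom) in enumerate(raw):
        key = (*atom.residue_id, atom.name)
        if key not in best:
            best[key] = (occ, listed, atom)
            order.append(key)
        elif occ > best[key][0]:
            best[key] = (occ, listed, atom)
    return [best[k][2] for k in order]


def read_pdb(path: str | Path, model: int = 0) -> ProteinStructure:
    """Parse a PDB v3.x file into a :class:`ProteinStructure`.

    All ATOM/HETATM records of the first model are kept (including
    hydrogens; downstream operations ignore them).  Alternate locations are
    resolved to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except Exception as exc:  # pragma: no cover - gemmi error text varies
        raise IOError(f"could not parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no coordinate records")
    raw: list[tuple[str, float, AtomRecord]] = []
    for chain in st[model]:
        for res in chain:
            het = res.het_flag == "H"
            for atom in res:
                rec = AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    element=atom.element.name.upper(),
                    residue_name=res.name,
                    residue_seq=res.seqid.num,
                    chain_id=chain.name,
                    coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                    is_hetero=het,
                    icode=(res.seqid.icode or "").strip(),
                    occupancy=atom.occ,
                )
                raw.append((atom.altloc, atom.occ, rec))
    atoms = _resolve_altlocs(raw)
    if not atoms:
        raise EmptyStructureError(f"{path} contains no ATOM/HETATM records")
    return ProteinStructure(atoms=atoms, id=path.stem)


def _to_gemmi(structure: ProteinStructure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id or "model"
    mdl = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple, gemmi.Residue] = {}
    for a in structure.atoms:
        ch = chains.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chains[a.chain_id] = ch
            mdl.add_chain(ch)
            ch = mdl[a.chain_id]
            chains[a.chain_id] = ch
        key = a.residue_id
        res = residues.get(key)
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_seq, a.icode or " ")
            res.het_flag = "H" if a.is_hetero else "A"
            ch.add_residue(res)
            res = ch[len(ch) - 1]
            residues[key] = res
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element.capitalize())
        atom.pos = gemmi.Position(*a.coords)
        atom.occ = a.occupancy
        atom.serial = a.serial
        res.add_atom(atom)
    st.add_model(mdl)
    st.setup_entities()
    return st


def write_pdb(structure: ProteinStructure | LigandMolecule, path: str | Path) -> Path:
    """Write a structure (or a bare ligand fragment) as fixed-column PDB."""
    if isinstance(structure, LigandMolecule):
        structure = ProteinStructure(atoms=structure.atoms, id=structure.residue_name)
    st = _to_gemmi(structure)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# Curation operations
# ---------------------------------------------------------------------------

def select_chain(
    structure: ProteinStructure,
    ligand: LigandMolecule,
    contact_cutoff: float = 5.0,
) -> ProteinStructure:
    """Keep only the chain bound to the inhibitor.

    The bound chain is the one whose minimum protein heavy-atom distance to
    any ligand heavy atom is smallest; ties are broken by chain label order.
    """
    chains = structure.chains
    if not chains:
        raise EmptyStructureError("structure has no chains")
    lig_xyz = ligand.coordinates()
    best: tuple[float, str] | None = None
    for cid in sorted(chains):
        xyz = np.array(
            [a.coords for a in structure.protein_atoms() if a.chain_id == cid],
            dtype=float,
        )
        if xyz.size == 0:
            continue
        d = np.sqrt(((xyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(axis=2)).min()
        if best is None or d < best[0] - 1e-9:
            best = (float(d), cid)
    if best is None or best[0] > contact_cutoff:
        raise NoBoundChainError(
            f"no chain within {contact_cutoff} A of ligand {ligand.residue_name!r}"
        )
    keep = best[1]
    return structure.subset([a for a in structure.atoms if a.chain_id == keep])


def strip_non_protein(
    structure: ProteinStructure, keep_ligand: str | None = None
) -> ProteinStructure:
    """Remove waters and hetero residues, optionally retaining one ligand.

    Amino-acid residues (including common modified residues such as MSE) are
    untouched.  Idempotent.
    """
    if keep_ligand is not None:
        names = {a.residue_name.upper() for a in structure.atoms}
        if keep_ligand.upper() not in names:
            raise MissingLigandError(
                f"ligand residue {keep_ligand!r} not present in structure"
            )
    kept = []
    for a in structure.atoms:
        name = a.residue_name.upper()
        if is_water(name):
            continue
        if is_protein_residue(name):
            kept.append(a)
        elif keep_ligand is not None and name == keep_ligand.upper():
            kept.append(a)
    if not any(is_protein_residue(a.residue_name) for a in kept):
        raise EmptyStructureError("no protein residues remain after stripping")
    return structure.subset(kept)


def extract_ligand(
    structure: ProteinStructure,
    residue_name: str,
    chain_id: str | None = None,
) -> LigandMolecule:
    """Extract the heavy atoms of a named ligand residue.

    Raises :class:`AmbiguousLigandError` when several copies of the residue
    exist and no chain is specified (the pipeline never guesses which copy
    seeded the crystal pocket).
    """
    target = residue_name.upper()
    groups: dict[tuple, list[AtomRecord]] = {}
    for a in structure.atoms:
        if a.residue_name.upper() != target:
            continue
        if chain_id is not None and a.chain_id != chain_id:
            continue
        groups.setdefault(a.residue_id, []).append(a)
    if not groups:
        where = f" in chain {chain_id}" if chain_id else ""
        raise MissingLigandError(f"residue {residue_name!r} not found{where}")
    if len(groups) > 1:
        copies = ", ".join(f"{c}/{s}{i}" for (c, s, i, _) in sorted(groups))
        raise AmbiguousLigandError(
            f"residue {residue_name!r} has {len(groups)} copies ({copies}); "
            "specify chain_id (and a unique copy) to disambiguate"
        )
    (atoms,) = groups.values()
    return LigandMolecule(atoms=atoms, residue_name=target)
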