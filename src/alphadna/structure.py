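"""PDB structure I/O and chain classification.

Structures are held as a flat, ordered list of heavy atoms plus a
per-chain classification (protein / dna / other) derived from the
residue-name vocabulary.  Parsing and serialisation go through biotite;
only the first MODEL of multi-model files is read, the
highest-occupancy altloc is kept, and HETATM records are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import biotite.structure as _struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Structure",
    "AMINO_ACIDS",
    "DNA_RESIDUES",
    "read_pdb",
    "write_pdb",
    "strip_dna",
]

#: The 20 standard amino-acid residue names.
AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLU", "GLN", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

#: Deoxyribonucleotide residue names, including legacy one-letter forms.
DNA_RESIDUES = frozenset({"DA", "DT", "DG", "DC", "A", "T", "G", "C"})

_HYDROGENS = frozenset({"H", "D"})


@dataclass(frozen=True)
class Atom:
    """A single heavy atom.

    ``residue_id`` is the triple (chain id, residue sequence number,
    insertion code) that identifies the parent residue; coordinates are
    in Angstroms.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: tuple[str, int, str]
    coord: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.residue_name:
            raise ValueError("residue_name must be non-empty")
        if not all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.serial}")

    @property
    def chain_id(self) -> str:
        return self.residue_id[0]

    @property
    def identity(self) -> tuple[str, int, str, str]:
        """(chain, resseq, icode, atom name) — stable across re-parsing."""
        return (*self.residue_id, self.name)


@dataclass
class Structure:
    """An ordered atomic model with per-chain classification."""

    atoms: list[Atom]
    chain_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {a.chain_id for a in self.atoms} - set(self.chain_class)
        if missing:
            self.chain_class.update(classify_chains(self.atoms, missing))

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in file order."""
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    def atoms_of_class(self, cls: str) -> list[Atom]:
        return [a for a in self.atoms if self.chain_class[a.chain_id] == cls]

    @property
    def protein_atoms(self) -> list[Atom]:
        return self.atoms_of_class("protein")

    @property
    def dna_atoms(self) -> list[Atom]:
        return self.atoms_of_class("dna")

    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)


def classify_chains(atoms: Iterable[Atom], chains: Iterable[str] | None = None) -> dict[str, str]:
    """Classify chains by residue-name vocabulary (majority vote).

    A chain is ``protein`` when its amino-acid residues outnumber its
    nucleotide residues, ``dna`` when nucleotides dominate, ``other``
    when neither vocabulary matches.
    """
    per_chain: dict[str, dict[tuple[int, str], str]] = {}
    for a in atoms:
        per_chain.setdefault(a.chain_id, {})[(a.residue_id[1], a.residue_id[2])] = a.residue_name
    wanted = set(per_chain) if chains is None else set(chains)
    out = {}
    for cid in wanted:
        names = list(per_chain.get(cid, {}).values())
        n_aa = sum(1 for n in names if n in AMINO_ACIDS)
        n_nt = sum(1 for n in names if n in DNA_RESIDUES)
        if n_aa == 0 and n_nt == 0:
            out[cid] = "other"
        elif n_aa >= n_nt:
            out[cid] = "protein"
        else:
            out[cid] = "dna"
    return out


def _from_atom_array(arr) -> Structure:
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(
            Atom(
                serial=int(arr.atom_id[i]),
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                residue_name=str(arr.res_name[i]),
                residue_id=(str(arr.chain_id[i]), int(arr.res_id[i]), str(arr.ins_code[i])),
                coord=tuple(float(x) for x in arr.coord[i]),
            )
        )
    return Structure(atoms=atoms)


def read_pdb(path: str | Path, heavy_atoms_only: bool = True) -> Structure:
    """Read the first model of a PDB file.

    Chains are classified from their residue names; hydrogens are
    dropped when ``heavy_atoms_only`` is set (the default).  HETATM
    records are always ignored.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If the file contains no ATOM records.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    pdb = PDBFile.read(str(path))
    try:
        arr = pdb.get_structure(model=1, altloc="occupancy", extra_fields=["atom_id"])
    except Exception as exc:  # malformed coordinates / no models
        raise ValueError(f"cannot parse ATOM records from {path}: {exc}") from exc
    arr = arr[~arr.hetero]
    if heavy_atoms_only:
        arr = arr[~np.isin(arr.element, list(_HYDROGENS))]
    if arr.array_length() == 0:
        raise ValueError(f"no ATOM records in {path}")
    st = _from_atom_array(arr)
    seen: set[tuple[int, str]] = set()
    for a in st.atoms:
        key = (a.serial, a.chain_id)
        if key in seen:
            raise ValueError(f"duplicate atom serial {a.serial} on chain {a.chain_id}")
        seen.add(key)
    return st


def strip_dna(structure: Structure) -> Structure:
    """Return the protein-only substructure (the DNA part removed).

    Atom order is preserved; the input is not modified.

    Raises
    ------
    ValueError
        If no protein atoms remain.
    """
    atoms = structure.protein_atoms
    if not atoms:
        raise ValueError("structure contains no protein atoms")
    chain_class = {c: k for c, k in structure.chain_class.items() if k == "protein"}
    return Structure(atoms=list(atoms), chain_class=chain_class)


def _to_atom_array(structure: Structure):
    n = len(structure.atoms)
    arr = _struc.AtomArray(n)
    arr.coord = structure.coords()
    arr.chain_id = np.array([a.chain_id for a in structure.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_id[1] for a in structure.atoms], dtype=int)
    arr.ins_code = np.array([a.residue_id[2] for a in structure.atoms], dtype="U1")
    arr.res_name = np.array([a.residue_name for a in structure.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in structure.atoms], dtype="U6")
    arr.element = np.array([a.element for a in structure.atoms], dtype="U2")
    return arr


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-column PDB ATOM records, TER between chains.

    Coordinates are emitted to 3 decimals; a ``read_pdb`` of the output
    reproduces the atom names, residue ids, chain classes and coordinates.
    """
    if not structure.atoms:
        raise ValueError("cannot write an empty structure")
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure))
    lines = [ln for ln in pdb.lines if ln.startswith("ATOM")]
    out: list[str] = []
    chain_ids = [a.chain_id for a in structure.atoms]
    for i, ln in enumerate(lines):
        out.append(ln)
        if i + 1 == len(lines) or chain_ids[i + 1] != chain_ids[i]:
            out.append("TER")
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")


def merge(structures: Iterable[Structure], renumber_serials: bool = True) -> Structure:
    """Concatenate structures, deduplicating chain ids where they collide."""
    alphabet = [chr(c) for c in range(ord("A"), ord("Z") + 1)] + [str(d) for d in range(10)]
    atoms: list[Atom] = []
    chain_class: dict[str, str] = {}
    serial = 0
    for st in structures:
        remap: dict[str, str] = {}
        for cid in st.chains():
            new = cid
            if new in chain_class:
                free = [c for c in alphabet if c not in chain_class and c not in remap.values()]
                if not free:
                    raise ValueError("chain-id collision unresolvable: alphabet exhausted")
                new = free[0]
            remap[cid] = new
            chain_class[new] = st.chain_class[cid]
        for a in st.atoms:
            serial += 1
            atoms.append(
                replace(
                    a,
                    serial=serial if renumber_serials else a.serial,
                    residue_id=(remap[a.chain_id], a.residue_id[1], a.residue_id[2]),
                )
            )
    return Structure(atoms=atoms, chain_class=chain_class)
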