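"""PDB structure I/O and rigid-body geometry primitives.

A complex is exactly two protein chains: the antigen (receptor) and the
nanobody (ligand). Structures are read with Biopython and reduced to heavy
atoms of the first model, first altloc; this matches the residue-level,
heavy-atom feature definitions used throughout the package and makes the
geometry independent of how upstream docking/refinement programs protonate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.Data.IUPACData import protein_letters_3to1_extended

__all__ = [
    "Atom",
    "Residue",
    "ComplexStructure",
    "read_complex",
    "write_complex",
    "chain_sequence",
    "superpose",
    "three_to_one",
    "MissingChainError",
    "EmptyStructureError",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1_extended.items()}


class MissingChainError(KeyError):
    """Requested chain id is absent from the PDB file."""


class EmptyStructureError(ValueError):
    """No usable ATOM records for a requested chain."""


def three_to_one(name3: str) -> str:
    """Map a 3-letter residue code to a 1-letter code; nonstandard -> 'X'.

    Codes outside the 20 standard amino acids (including MSE and other
    modified residues) collapse to 'X' so that downstream per-amino-acid
    counts and descriptor sums only ever see standard residues.
    """
    one = _3TO1.get(name3.strip().upper(), "X")
    return one if one in "ACDEFGHIKLMNPQRSTVWY" else "X"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float))
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError("atom coordinates must be a finite 3-vector")


@dataclass
class Residue:
    chain_id: str
    resseq: int
    icode: str
    name3: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def code1(self) -> str:
        return three_to_one(self.name3)

    @property
    def res_id(self) -> tuple[str, int, str]:
        """(chain, author seq number, insertion code) — the pose-matching key."""
        return (self.chain_id, self.resseq, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass
class ComplexStructure:
    """Two-chain Nb-Ag complex: antigen chain + nanobody chain."""

    antigen: list[Residue]
    nanobody: list[Residue]

    def __post_init__(self):
        if not self.antigen or not self.nanobody:
            raise EmptyStructureError("both chains must contain at least one residue")

    @property
    def antigen_chain_id(self) -> str:
        return self.antigen[0].chain_id

    @property
    def nanobody_chain_id(self) -> str:
        return self.nanobody[0].chain_id

    def chain_coords(self, chain: str = "nanobody", atoms: Sequence[str] | None = None) -> np.ndarray:
        residues = self.nanobody if chain == "nanobody" else self.antigen
        pts = []
        for r in residues:
            for a in r.atoms:
                if atoms is None or a.name in atoms:
                    pts.append(a.xyz)
        return np.array(pts, dtype=float).reshape(-1, 3)


def _guess_element(bio_atom) -> str:
    el = (bio_atom.element or "").strip()
    if el:
        return el.upper()
    # fall back on the first alphabetic character of the atom name
    for ch in bio_atom.get_name():
        if ch.isalpha():
            return ch.upper()
    return "X"


def _extract_chain(model, chain_id: str, path) -> list[Residue]:
    if chain_id not in [c.id for c in model]:
        raise MissingChainError(f"chain {chain_id!r} not found in {path}")
    residues: list[Residue] = []
    for bio_res in model[chain_id]:
        hetflag, resseq, icode = bio_res.id
        name3 = bio_res.get_resname().strip()
        if hetflag != " " and ("CA" not in bio_res or name3.upper() in ("HOH", "WAT")):
            continue  # waters, ligands, ions; modified amino acids have a CA
        atoms: list[Atom] = []
        for bio_atom in bio_res:
            el = _guess_element(bio_atom)
            if el in ("H", "D"):
                continue
            # keep the first altloc only (Biopython yields the highest-occupancy
            # conformer for disordered atoms by default)
            atoms.append(Atom(bio_atom.get_name(), el, np.array(bio_atom.get_coord(), dtype=float)))
        if atoms:
            residues.append(Residue(chain_id, int(resseq), icode.strip(), name3, atoms))
    if not residues:
        raise EmptyStructureError(f"chain {chain_id!r} in {path} has no protein ATOM records")
    return residues


def read_complex(path, antigen_chain: str = "A", nanobody_chain: str = "H") -> ComplexStructure:
    """Read a two-chain complex from a PDB file.

    Only heavy atoms of the first model are kept; residue order follows file
    order. Raises :class:`MissingChainError` if a chain id is absent and
    :class:`EmptyStructureError` when a chain carries no protein atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("complex", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise EmptyStructureError(f"{path} contains no models")
    return ComplexStructure(
        antigen=_extract_chain(model, antigen_chain, path),
        nanobody=_extract_chain(model, nanobody_chain, path),
    )


def write_complex(complex_: ComplexStructure, path) -> None:
    """Write minimal wwPDB v3.3 ATOM records (antigen chain then nanobody)."""
    lines = []
    serial = 1
    for residues in (complex_.antigen, complex_.nanobody):
        for res in residues:
            for atom in res.atoms:
                name = atom.name
                # column-13 alignment rule: 1-letter elements start in col 14
                padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
                x, y, z = atom.xyz
                lines.append(
                    f"ATOM  {serial:>5d} {padded} {res.name3:>3s} {res.chain_id}"
                    f"{res.resseq:>4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def chain_sequence(residues: Iterable[Residue]) -> str:
    """One-letter sequence of a residue list; nonstandard residues become X."""
    residues = list(residues)
    if not residues:
        raise ValueError("empty residue list")
    return "".join(r.code1 for r in residues)


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"point count mismatch: {mobile.shape} vs {target.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    H = (mobile - mu_m).T @ (target - mu_t)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_m
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_fixed(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between paired coordinate sets without superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("point count mismatch")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
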