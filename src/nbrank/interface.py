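"""Interface detection, CDR annotation, and the contact feature block.

The paratope/epitope is defined by a heavy-atom distance criterion
(default 5.0 A, inclusive) — the same contact convention DockQ uses for
Fnat, so contact features and quality labels share one notion of
"interface". CDR loops are taken from user-supplied spans when available;
otherwise a conserved-anchor heuristic locates them from the sequence
(the two framework cysteines and the J-segment W-G-x-G motif).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from nbrank.structio import ComplexStructure

__all__ = [
    "InterfaceDefinition",
    "CDRAnnotation",
    "InterfaceResidues",
    "ContactFeatures",
    "detect_interface",
    "annotate_cdrs",
    "contact_features",
    "MissingCDRError",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Chothia-like positional windows relative to the two conserved framework
# cysteines (VH numbering: Cys22 / Cys92, CDR-H1 26-32, CDR-H2 52-56).
_CDR1_OFFSET = (4, 11)   # [cys1+4, cys1+11)
_CDR2_OFFSET = (30, 35)  # [cys1+30, cys1+35)
_CDR3_START_OFFSET = 3   # cdr3 = [cys2+3, W of the WGxG anchor)
_WGXG = re.compile(r"WG.G")


class MissingCDRError(ValueError):
    """A CDR loop could not be located; the complex is rejected."""


@dataclass(frozen=True)
class InterfaceDefinition:
    contact_cutoff: float = 5.0

    def __post_init__(self):
        if self.contact_cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


@dataclass(frozen=True)
class CDRAnnotation:
    """Half-open 0-based positional spans of the three CDR loops."""

    cdr1: tuple[int, int]
    cdr2: tuple[int, int]
    cdr3: tuple[int, int]

    def __post_init__(self):
        spans = [self.cdr1, self.cdr2, self.cdr3]
        for i, (s, e) in enumerate(spans, start=1):
            if not (0 <= s < e):
                raise MissingCDRError(f"cdr{i} span [{s},{e}) is empty or negative")
        if not (self.cdr1[1] <= self.cdr2[0] and self.cdr2[1] <= self.cdr3[0]):
            raise MissingCDRError("CDR spans must be ordered and non-overlapping")

    def positions(self, loop: int) -> set[int]:
        s, e = (self.cdr1, self.cdr2, self.cdr3)[loop - 1]
        return set(range(s, e))

    def all_positions(self) -> set[int]:
        return self.positions(1) | self.positions(2) | self.positions(3)

    def length(self, loop: int) -> int:
        s, e = (self.cdr1, self.cdr2, self.cdr3)[loop - 1]
        return e - s


@dataclass(frozen=True)
class InterfaceResidues:
    """0-based positional indices of interface residues on each chain."""

    paratope: frozenset[int]
    epitope: frozenset[int]


@dataclass
class ContactFeatures:
    n_paratope: int
    n_epitope: int
    n_interacting_cdr: tuple[int, int, int]
    len_cdr: tuple[int, int, int]
    frac_cdr_in_paratope: float
    frac_interacting_cdr_vs_len: tuple[float, float, float]
    aa_count_paratope: dict[str, int]
    aa_count_epitope: dict[str, int]

    def to_vector(self) -> np.ndarray:
        """Flatten to the fixed 52-feature contact block (schema order)."""
        vals = [
            float(self.n_paratope),
            float(self.n_epitope),
            *[float(v) for v in self.n_interacting_cdr],
            *[float(v) for v in self.len_cdr],
            float(self.frac_cdr_in_paratope),
            *[float(v) for v in self.frac_interacting_cdr_vs_len],
            *[float(self.aa_count_paratope[a]) for a in AMINO_ACIDS],
            *[float(self.aa_count_epitope[a]) for a in AMINO_ACIDS],
        ]
        return np.array(vals, dtype=float)

    @staticmethod
    def feature_names() -> list[str]:
        return (
            ["n_paratope", "n_epitope"]
            + [f"n_interacting_cdr{k}" for k in (1, 2, 3)]
            + [f"len_cdr{k}" for k in (1, 2, 3)]
            + ["frac_cdr_in_paratope"]
            + [f"frac_interacting_cdr{k}_vs_len" for k in (1, 2, 3)]
            + [f"aa_count_paratope_{a}" for a in AMINO_ACIDS]
            + [f"aa_count_epitope_{a}" for a in AMINO_ACIDS]
        )


def _chain_atom_table(residues) -> tuple[np.ndarray, np.ndarray]:
    """All heavy-atom coordinates of a chain with their residue indices."""
    coords, owner = [], []
    for i, res in enumerate(residues):
        for atom in res.atoms:
            coords.append(atom.xyz)
            owner.append(i)
    return np.asarray(coords, dtype=float).reshape(-1, 3), np.asarray(owner, dtype=int)


def residue_contact_pairs(complex_: ComplexStructure, cutoff: float) -> set[tuple[int, int]]:
    """Cross-chain residue index pairs with any heavy-atom distance <= cutoff.

    Pairs are (antigen position, nanobody position), 0-based. Uses a KD-tree
    over atoms of both chains; the inclusive comparison makes a pair at
    exactly the cutoff a contact.
    """
    ag_xyz, ag_owner = _chain_atom_table(complex_.antigen)
    nb_xyz, nb_owner = _chain_atom_table(complex_.nanobody)
    tree_ag = cKDTree(ag_xyz)
    tree_nb = cKDTree(nb_xyz)
    pairs = tree_ag.query_ball_tree(tree_nb, r=cutoff)  # inclusive
    out: set[tuple[int, int]] = set()
    for i_ag, nb_hits in enumerate(pairs):
        for j_nb in nb_hits:
            out.add((int(ag_owner[i_ag]), int(nb_owner[j_nb])))
    return out


def detect_interface(
    complex_: ComplexStructure, definition: InterfaceDefinition | None = None
) -> InterfaceResidues:
    """Paratope/epitope residues: any heavy-atom pair within the cutoff."""
    definition = definition or InterfaceDefinition()
    pairs = residue_contact_pairs(complex_, definition.contact_cutoff)
    return InterfaceResidues(
        paratope=frozenset(j for _, j in pairs),
        epitope=frozenset(i for i, _ in pairs),
    )


def annotate_cdrs(nb_sequence: str, user_spans: dict | None = None) -> CDRAnnotation:
    """Locate the three CDR loops on a nanobody sequence.

    ``user_spans`` (``{"cdr1": [s, e), ...}``, 0-based half-open) wins when
    given and is only validated. Otherwise the built-in anchor heuristic is
    used: the first framework cysteine anchors Chothia-like CDR1/CDR2
    windows, and CDR3 runs from three residues past the second cysteine to
    the tryptophan of the W-G-x-G J-anchor.
    """
    n = len(nb_sequence)
    if user_spans is not None:
        try:
            ann = CDRAnnotation(
                cdr1=tuple(user_spans["cdr1"]),
                cdr2=tuple(user_spans["cdr2"]),
                cdr3=tuple(user_spans["cdr3"]),
            )
        except KeyError as exc:
            raise MissingCDRError(f"user spans missing {exc}")
        if ann.cdr3[1] > n:
            raise MissingCDRError("user CDR spans extend past the sequence")
        return ann

    if n < 60:
        raise MissingCDRError("sequence too short to be a nanobody variable domain")
    cys1 = nb_sequence.find("C", 10, 35)
    if cys1 < 0:
        raise MissingCDRError("first framework cysteine (around position 22) not found")
    # second framework cysteine: last C before the J-anchor region
    cys2 = nb_sequence.rfind("C", cys1 + 40, n - 6)
    if cys2 < 0:
        raise MissingCDRError("second framework cysteine (around position 92) not found")
    m = _WGXG.search(nb_sequence, cys2 + _CDR3_START_OFFSET + 1)
    if m is None:
        raise MissingCDRError("W-G-x-G J-segment anchor not found after the second cysteine")
    cdr1 = (cys1 + _CDR1_OFFSET[0], cys1 + _CDR1_OFFSET[1])
    cdr2 = (cys1 + _CDR2_OFFSET[0], cys1 + _CDR2_OFFSET[1])
    cdr3 = (cys2 + _CDR3_START_OFFSET, m.start())
    try:
        return CDRAnnotation(cdr1=cdr1, cdr2=cdr2, cdr3=cdr3)
    except MissingCDRError as exc:
        raise MissingCDRError(f"anchor-derived spans invalid: {exc}")


def contact_features(
    iface: InterfaceResidues, cdrs: CDRAnnotation, complex_: ComplexStructure
) -> ContactFeatures:
    """The 52-feature contact block.

    Per-loop interaction fractions are |paratope ∩ CDRk| / |CDRk|;
    ``frac_cdr_in_paratope`` is the proportion of the paratope falling in
    any CDR (0 for an empty paratope). Amino-acid counts cover the 20
    standard residues; X contributes to the totals but to no letter.
    """
    paratope = set(iface.paratope)
    n_inter = tuple(len(paratope & cdrs.positions(k)) for k in (1, 2, 3))
    lens = tuple(cdrs.length(k) for k in (1, 2, 3))
    in_any_cdr = len(paratope & cdrs.all_positions())
    frac_in = in_any_cdr / len(paratope) if paratope else 0.0
    frac_vs_len = tuple(n_inter[k] / lens[k] for k in range(3))

    def aa_counts(residues, positions) -> dict[str, int]:
        counts = {a: 0 for a in AMINO_ACIDS}
        for pos in positions:
            c = residues[pos].code1
            if c in counts:
                counts[c] += 1
        return counts

    return ContactFeatures(
        n_paratope=len(paratope),
        n_epitope=len(iface.epitope),
        n_interacting_cdr=n_inter,
        len_cdr=lens,
        frac_cdr_in_paratope=frac_in,
        frac_interacting_cdr_vs_len=frac_vs_len,
        aa_count_paratope=aa_counts(complex_.nanobody, paratope),
        aa_count_epitope=aa_counts(complex_.antigen, iface.epitope),
    )
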