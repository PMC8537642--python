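"""The 248-column pose feature schema and its building blocks.

Block layout (fixed order):

    contact (52) | rosetta (20) | foldx (44) | property_paratope (66) | property_epitope (66)

The contact block comes from :mod:`nbrank.interface`; the two energy
blocks are parsed from externally computed Rosetta InterfaceAnalyzer score
files and FoldX AnalyseComplex tab files (this package never runs either
program); the property blocks are sums of 66 per-amino-acid descriptor
values over the paratope and epitope residues.

Missing energy values are explicit (NaN), never silently zero: the
downstream gradient-boosted trees route missing values natively, so poses
without external energy runs stay usable in contact+property mode.

The descriptor table ships as packaged data
(``data/aa_descriptors_synthetic.csv``): ten scale families of sizes
3+10+5+6+5+8+8+8+10+3 = 66. The Kidera-factor (KF1-10) and z-scale (Z1-5)
columns transcribe the published values; the remaining eight families are
deterministic synthetic stand-ins on a realistic zero-mean unit scale,
frozen at package build time, because the original tables are not
redistributable here. Any 20 x 66 table with the same column names can be
substituted via :func:`load_descriptor_table`.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nbrank.interface import ContactFeatures

__all__ = [
    "DESCRIPTOR_FAMILIES",
    "ROSETTA_TERMS",
    "FOLDX_TERMS",
    "DescriptorTable",
    "EnergyFeatures",
    "FeatureSchema",
    "PoseRecord",
    "load_descriptor_table",
    "property_profile",
    "parse_rosetta_scores",
    "parse_foldx_complex",
    "assemble_features",
    "EnergyParseError",
    "SchemaError",
]

DESCRIPTOR_FAMILIES = {
    "cruciani": ["PP1", "PP2", "PP3"],
    "kidera": [f"KF{i}" for i in range(1, 11)],
    "zscales": [f"Z{i}" for i in range(1, 6)],
    "fasgai": [f"F{i}" for i in range(1, 7)],
    "tscales": [f"T{i}" for i in range(1, 6)],
    "vhse": [f"VHSE{i}" for i in range(1, 9)],
    "protfp": [f"ProtFP{i}" for i in range(1, 9)],
    "stscales": [f"ST{i}" for i in range(1, 9)],
    "blosum_indices": [f"BLOSUM{i}" for i in range(1, 11)],
    "mswhim": [f"MSWHIM{i}" for i in range(1, 4)],
}
DESCRIPTOR_COLUMNS = [c for cols in DESCRIPTOR_FAMILIES.values() for c in cols]
assert len(DESCRIPTOR_COLUMNS) == 66

# Canonical Rosetta InterfaceAnalyzer score columns (20 slots).
ROSETTA_TERMS = (
    "dG_separated",
    "dG_separated/dSASAx100",
    "dG_cross",
    "dG_cross/dSASAx100",
    "dSASA_int",
    "dSASA_hphobic",
    "dSASA_polar",
    "delta_unsatHbonds",
    "hbond_E_fraction",
    "hbonds_int",
    "nres_int",
    "nres_all",
    "packstat",
    "sc_value",
    "side1_normalized",
    "side1_score",
    "side2_normalized",
    "side2_score",
    "complex_normalized",
    "complexed_sasa",
)

# Canonical FoldX AnalyseComplex slots (44): 30 group-pair interaction
# terms plus 7 per-chain-group terms x 2 groups (group1 = Ag, group2 = Nb).
_FOLDX_PAIR_TERMS = (
    "interaction_energy",
    "backbone_hbond",
    "sidechain_hbond",
    "van_der_waals",
    "electrostatics",
    "solvation_polar",
    "solvation_hydrophobic",
    "van_der_waals_clashes",
    "entropy_sidechain",
    "entropy_mainchain",
    "sloop_entropy",
    "mloop_entropy",
    "cis_bond",
    "torsional_clash",
    "backbone_clash",
    "helix_dipole",
    "water_bridge",
    "disulfide",
    "electrostatic_kon",
    "partial_covalent_bonds",
    "energy_ionisation",
    "entropy_complex",
    "number_of_residues",
    "interface_residues",
    "interface_residues_clashing",
    "interface_residues_vdw_clashing",
    "interface_residues_bb_clashing",
    "intraclashes_group1",
    "intraclashes_group2",
    "stability_energy",
)
_FOLDX_GROUP_TERMS = (
    "total_energy",
    "backbone_hbond",
    "sidechain_hbond",
    "van_der_waals",
    "electrostatics",
    "solvation_polar",
    "solvation_hydrophobic",
)
FOLDX_TERMS = _FOLDX_PAIR_TERMS + tuple(
    f"{t}_{g}" for g in ("group1", "group2") for t in _FOLDX_GROUP_TERMS
)
assert len(ROSETTA_TERMS) == 20 and len(FOLDX_TERMS) == 44


class EnergyParseError(ValueError):
    """Energy table file malformed or empty."""


class SchemaError(ValueError):
    """Feature inputs do not conform to the schema mode."""


@dataclass(frozen=True)
class DescriptorTable:
    """20 standard amino acids x 66 named descriptor values."""

    values: pd.DataFrame

    def __post_init__(self):
        df = self.values
        if list(df.columns) != DESCRIPTOR_COLUMNS:
            raise ValueError("descriptor table must have exactly the 66 canonical columns")
        if sorted(df.index) != sorted("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("descriptor table must cover the 20 standard amino acids")
        if df.isna().any().any():
            raise ValueError("descriptor table must be complete")

    def row(self, aa: str) -> np.ndarray:
        return self.values.loc[aa].to_numpy(dtype=float)


def load_descriptor_table(path=None) -> DescriptorTable:
    """Load the packaged descriptor table, or a user-supplied CSV."""
    if path is None:
        ref = importlib.resources.files("nbrank") / "data" / "aa_descriptors_synthetic.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, index_col="aa")
    else:
        df = pd.read_csv(Path(path), index_col="aa")
    return DescriptorTable(values=df)


def property_profile(residues, table: DescriptorTable) -> np.ndarray:
    """Elementwise sum of descriptor rows over a residue collection.

    ``residues`` may be Residue objects or 1-letter codes; nonstandard
    residues (code X) contribute zero. The empty collection sums to zeros.
    """
    total = np.zeros(66, dtype=float)
    for r in residues:
        code = r if isinstance(r, str) else r.code1
        if code in table.values.index:
            total += table.row(code)
    return total


@dataclass
class EnergyFeatures:
    """Named Rosetta (20) + FoldX (44) energy slots; None marks missing."""

    rosetta: dict[str, float | None] = field(
        default_factory=lambda: {t: None for t in ROSETTA_TERMS}
    )
    foldx: dict[str, float | None] = field(
        default_factory=lambda: {t: None for t in FOLDX_TERMS}
    )

    def __post_init__(self):
        if set(self.rosetta) != set(ROSETTA_TERMS):
            raise ValueError("rosetta slots must match the 20 canonical terms")
        if set(self.foldx) != set(FOLDX_TERMS):
            raise ValueError("foldx slots must match the 44 canonical terms")

    def rosetta_vector(self) -> np.ndarray:
        return np.array(
            [np.nan if self.rosetta[t] is None else self.rosetta[t] for t in ROSETTA_TERMS]
        )

    def foldx_vector(self) -> np.ndarray:
        return np.array(
            [np.nan if self.foldx[t] is None else self.foldx[t] for t in FOLDX_TERMS]
        )


def _normalize(name: str) -> str:
    return re.sub(r"[^a-z0-9/_]+", "_", name.strip().lower()).strip("_")


_ROSETTA_BY_NORM = {_normalize(t): t for t in ROSETTA_TERMS}
_FOLDX_BY_NORM = {_normalize(t): t for t in FOLDX_TERMS}


def parse_rosetta_scores(path) -> EnergyFeatures:
    """Parse a Rosetta score file (InterfaceAnalyzer output).

    Handles both plain whitespace-delimited tables and the ``SCORE:``-tagged
    format. Canonical columns are mapped by name, unknown columns ignored,
    absent canonical columns marked missing. The first data row is used.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    rows = []
    for ln in lines:
        if ln.startswith("SEQUENCE:"):
            continue
        if ln.startswith("SCORE:"):
            ln = ln[len("SCORE:"):].strip()
        rows.append(ln.split())
    if not rows:
        raise EnergyParseError(f"{path}: empty score file")
    header = rows[0]
    data = [r for r in rows[1:] if len(r) == len(header)]
    if not data:
        raise EnergyParseError(f"{path}: no data rows matching the header")
    feats = EnergyFeatures()
    for col, val in zip(header, data[0]):
        slot = _ROSETTA_BY_NORM.get(_normalize(col))
        if slot is not None:
            try:
                feats.rosetta[slot] = float(val)
            except ValueError:
                pass
    return feats


def parse_foldx_complex(path) -> EnergyFeatures:
    """Parse a FoldX AnalyseComplex tab-delimited output file.

    Metadata lines before the header are skipped; the header row is the
    first line whose tab-split tokens include a recognizable canonical
    column. Absent canonical columns are marked missing.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    header_idx = None
    for i, ln in enumerate(lines):
        tokens = [_normalize(t) for t in ln.split("\t")]
        if sum(t in _FOLDX_BY_NORM for t in tokens) >= 3 or "pdb" in tokens:
            header_idx = i
            break
    if header_idx is None or header_idx + 1 >= len(lines):
        raise EnergyParseError(f"{path}: no recognizable header/data in FoldX table")
    header = lines[header_idx].split("\t")
    values = lines[header_idx + 1].split("\t")
    feats = EnergyFeatures()
    for col, val in zip(header, values):
        slot = _FOLDX_BY_NORM.get(_normalize(col))
        if slot is not None:
            try:
                feats.foldx[slot] = float(val)
            except ValueError:
                pass
    return feats


_ALL_BLOCKS = ("contact", "rosetta", "foldx", "property")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, named feature columns with block tags.

    Full mode is exactly 248 columns: 52 contact, 20 rosetta, 44 foldx and
    132 property (66 descriptors x paratope/epitope).
    """

    blocks: tuple[str, ...] = _ALL_BLOCKS

    def __post_init__(self):
        if not self.blocks:
            raise SchemaError("schema needs at least one block")
        unknown = set(self.blocks) - set(_ALL_BLOCKS)
        if unknown:
            raise SchemaError(f"unknown blocks: {sorted(unknown)}")
        # keep canonical block order regardless of user order
        object.__setattr__(
            self, "blocks", tuple(b for b in _ALL_BLOCKS if b in self.blocks)
        )
        if self.blocks == _ALL_BLOCKS and len(self.column_names()) != 248:
            raise SchemaError("full-mode schema must have exactly 248 columns")

    def column_names(self) -> list[str]:
        names: list[str] = []
        if "contact" in self.blocks:
            names += ContactFeatures.feature_names()
        if "rosetta" in self.blocks:
            names += [f"rosetta_{t}" for t in ROSETTA_TERMS]
        if "foldx" in self.blocks:
            names += [f"foldx_{t}" for t in FOLDX_TERMS]
        if "property" in self.blocks:
            names += [f"{c}_paratope" for c in DESCRIPTOR_COLUMNS]
            names += [f"{c}_epitope" for c in DESCRIPTOR_COLUMNS]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate column names")
        return names

    def block_tags(self) -> list[str]:
        tags: list[str] = []
        sizes = {"contact": 52, "rosetta": 20, "foldx": 44, "property": 132}
        for b in self.blocks:
            tags += [b] * sizes[b]
        return tags

    @property
    def n_columns(self) -> int:
        return len(self.column_names())

    def fingerprint(self) -> str:
        import hashlib

        return hashlib.sha256("|".join(self.column_names()).encode()).hexdigest()[:16]


def assemble_features(
    contact: ContactFeatures | None,
    energy: EnergyFeatures | None,
    props_paratope: np.ndarray | None,
    props_epitope: np.ndarray | None,
    schema: FeatureSchema,
) -> np.ndarray:
    """Concatenate the blocks the schema enables, in fixed order.

    Missing energy values propagate as NaN. Raises :class:`SchemaError`
    when a required block input is absent or the wrong size.
    """
    parts: list[np.ndarray] = []
    if "contact" in schema.blocks:
        if contact is None:
            raise SchemaError("schema includes contact block but none given")
        parts.append(contact.to_vector())
    if "rosetta" in schema.blocks or "foldx" in schema.blocks:
        energy = energy if energy is not None else EnergyFeatures()
        if "rosetta" in schema.blocks:
            parts.append(energy.rosetta_vector())
        if "foldx" in schema.blocks:
            parts.append(energy.foldx_vector())
    if "property" in schema.blocks:
        if props_paratope is None or props_epitope is None:
            raise SchemaError("schema includes property block but profiles missing")
        pp = np.asarray(props_paratope, dtype=float)
        pe = np.asarray(props_epitope, dtype=float)
        if pp.shape != (66,) or pe.shape != (66,):
            raise SchemaError("property profiles must be 66-vectors")
        parts.append(pp)
        parts.append(pe)
    vec = np.concatenate(parts)
    if vec.shape != (schema.n_columns,):
        raise SchemaError(f"assembled {vec.shape[0]} values for a {schema.n_columns}-column schema")
    return vec


@dataclass
class PoseRecord:
    """One refined pose: identity, feature vector, quality label."""

    complex_id: str
    docking_mode: str
    parent_id: str
    refined_id: str
    features: np.ndarray
    dockq: float
    label: int

    def key(self) -> tuple[str, str, str]:
        return (self.complex_id, self.parent_id, self.refined_id)


def records_to_frame(records: list[PoseRecord], schema: FeatureSchema) -> pd.DataFrame:
    """Tabulate PoseRecords: identity + label columns then feature columns."""
    cols = schema.column_names()
    meta = pd.DataFrame(
        {
            "complex_id": [r.complex_id for r in records],
            "docking_mode": [r.docking_mode for r in records],
            "parent_id": [r.parent_id for r in records],
            "refined_id": [r.refined_id for r in records],
            "dockq": [r.dockq for r in records],
            "label": [r.label for r in records],
        }
    )
    X = pd.DataFrame(
        np.vstack([r.features for r in records]) if records else np.empty((0, len(cols))),
        columns=cols,
    )
    return pd.concat([meta, X], axis=1)


def frame_to_records(frame: pd.DataFrame, schema: FeatureSchema) -> list[PoseRecord]:
    """Inverse of :func:`records_to_frame`."""
    cols = schema.column_names()
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise SchemaError(f"feature table lacks schema columns, e.g. {missing[:3]}")
    X = frame[cols].to_numpy(dtype=float)
    return [
        PoseRecord(
            complex_id=str(row.complex_id),
            docking_mode=str(row.docking_mode),
            parent_id=str(row.parent_id),
            refined_id=str(row.refined_id),
            features=X[i],
            dockq=float(row.dockq),
            label=int(row.label),
        )
        for i, row in enumerate(frame.itertuples(index=False))
    ]
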