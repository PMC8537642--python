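"""Docking quality assessment: Fnat, iRMS, LRMS, DockQ, CAPRI class, label.

DockQ combines three CAPRI-style components into one [0, 1] score:

    DockQ = ( Fnat + 1/(1+(iRMS/d1)^2) + 1/(1+(LRMS/d2)^2) ) / 3

with d1 = 1.5 A and d2 = 8.5 A. Native contacts use a 5 A heavy-atom
cutoff; the interface for iRMS is every native residue with a cross-chain
heavy atom within 10 A. The receptor is the antigen, the ligand the
nanobody. A pose is native-like (label 1) when DockQ >= 0.23, the
acceptable-quality boundary; below that it is an incorrect/non-native pose.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from nbrank.structio import (
    BACKBONE_ATOMS,
    ComplexStructure,
    read_complex,
    rmsd_fixed,
    superpose,
)
from nbrank.interface import residue_contact_pairs

__all__ = [
    "PoseQuality",
    "QualityParams",
    "DegenerateNativeError",
    "native_contacts",
    "fnat",
    "lrms",
    "irms",
    "dockq_score",
    "label_pose",
    "capri_class",
    "evaluate_pose",
    "batch_quality",
]

CAPRI_CLASSES = ("Incorrect", "Acceptable", "Medium", "High")


class DegenerateNativeError(ValueError):
    """Native complex has no interface; quality is undefined."""


@dataclass(frozen=True)
class QualityParams:
    fnat_cutoff: float = 5.0
    iface_cutoff: float = 10.0
    d1: float = 1.5
    d2: float = 8.5
    native_threshold: float = 0.23

    def __post_init__(self):
        if min(self.fnat_cutoff, self.iface_cutoff, self.d1, self.d2, self.native_threshold) <= 0:
            raise ValueError("all quality parameters must be positive")


@dataclass(frozen=True)
class PoseQuality:
    fnat: float
    irms: float
    lrms: float
    dockq: float
    capri: str
    label: int


ResPair = tuple[tuple[str, int, str], tuple[str, int, str]]


def native_contacts(complex_: ComplexStructure, cutoff: float = 5.0) -> set[ResPair]:
    """Cross-chain residue-id pairs with any heavy-atom distance <= cutoff."""
    pairs = residue_contact_pairs(complex_, cutoff)
    return {
        (complex_.antigen[i].res_id, complex_.nanobody[j].res_id) for i, j in pairs
    }


def fnat(model: ComplexStructure, native: ComplexStructure, params: QualityParams | None = None) -> float:
    """Fraction of native residue contacts preserved in the model."""
    params = params or QualityParams()
    ref = native_contacts(native, params.fnat_cutoff)
    if not ref:
        raise DegenerateNativeError("native complex has zero cross-chain contacts")
    mod = native_contacts(model, params.fnat_cutoff)
    return len(mod & ref) / len(ref)


def _backbone_map(residues) -> dict[tuple, np.ndarray]:
    out = {}
    for res in residues:
        for name in BACKBONE_ATOMS:
            atom = res.atom(name)
            if atom is not None:
                out[(res.res_id, name)] = atom.xyz
    return out


def _paired_backbone(model_res, native_res, keep_ids=None):
    """Matched backbone coordinate arrays (model, native) over shared atoms."""
    mod = _backbone_map(model_res)
    nat = _backbone_map(native_res)
    keys = [k for k in nat if k in mod and (keep_ids is None or k[0] in keep_ids)]
    keys.sort(key=lambda k: (k[0], BACKBONE_ATOMS.index(k[1])))
    m = np.array([mod[k] for k in keys], dtype=float).reshape(-1, 3)
    n = np.array([nat[k] for k in keys], dtype=float).reshape(-1, 3)
    return m, n


def lrms(model: ComplexStructure, native: ComplexStructure, params: QualityParams | None = None) -> float:
    """Ligand RMSD: nanobody backbone RMSD after antigen-backbone superposition."""
    m_rec, n_rec = _paired_backbone(model.antigen, native.antigen)
    if len(m_rec) < 3:
        raise ValueError("fewer than 3 shared antigen backbone atoms")
    R, t, _ = superpose(m_rec, n_rec)
    m_lig, n_lig = _paired_backbone(model.nanobody, native.nanobody)
    if len(m_lig) < 3:
        raise ValueError("fewer than 3 shared nanobody backbone atoms")
    return rmsd_fixed(m_lig @ R.T + t, n_lig)


def irms(model: ComplexStructure, native: ComplexStructure, params: QualityParams | None = None) -> float:
    """Interface RMSD: backbone RMSD over native 10 A interface residues
    after optimal superposition on those same atoms."""
    params = params or QualityParams()
    pairs = residue_contact_pairs(native, params.iface_cutoff)
    if not pairs:
        raise DegenerateNativeError("native complex has an empty interface")
    iface_ids = {native.antigen[i].res_id for i, _ in pairs} | {
        native.nanobody[j].res_id for _, j in pairs
    }
    m_a, n_a = _paired_backbone(model.antigen, native.antigen, keep_ids=iface_ids)
    m_b, n_b = _paired_backbone(model.nanobody, native.nanobody, keep_ids=iface_ids)
    m = np.vstack([m_a, m_b])
    n = np.vstack([n_a, n_b])
    if len(m) < 3:
        raise ValueError("fewer than 3 shared interface backbone atoms")
    _, _, fitted_rmsd = superpose(m, n)
    return fitted_rmsd


def dockq_score(fnat_value: float, irms_value: float, lrms_value: float, params: QualityParams | None = None) -> float:
    params = params or QualityParams()
    term_i = 1.0 / (1.0 + (irms_value / params.d1) ** 2)
    term_l = 1.0 / (1.0 + (lrms_value / params.d2) ** 2)
    return (fnat_value + term_i + term_l) / 3.0


def capri_class(dockq: float) -> str:
    """CAPRI band: [0,0.23) Incorrect, [0.23,0.49) Acceptable,
    [0.49,0.80) Medium, [0.80,1.0] High."""
    if not (0.0 <= dockq <= 1.0):
        raise ValueError(f"DockQ score {dockq} outside [0, 1]")
    if dockq < 0.23:
        return "Incorrect"
    if dockq < 0.49:
        return "Acceptable"
    if dockq < 0.80:
        return "Medium"
    return "High"


def label_pose(dockq: float, params: QualityParams | None = None) -> tuple[int, str]:
    """Binary nativeness label and CAPRI class. Label 0 iff DockQ < 0.23."""
    params = params or QualityParams()
    if not (0.0 <= dockq <= 1.0):
        raise ValueError(f"DockQ score {dockq} outside [0, 1]")
    return (0 if dockq < params.native_threshold else 1), capri_class(dockq)


def evaluate_pose(model: ComplexStructure, native: ComplexStructure, params: QualityParams | None = None) -> PoseQuality:
    """Full quality assessment of a model pose against the native complex."""
    params = params or QualityParams()
    f = fnat(model, native, params)
    i = irms(model, native, params)
    l = lrms(model, native, params)
    q = dockq_score(f, i, l, params)
    q = min(max(q, 0.0), 1.0)
    label, capri = label_pose(q, params)
    return PoseQuality(fnat=f, irms=i, lrms=l, dockq=q, capri=capri, label=label)


def batch_quality(manifest_path, out_path, antigen_chain: str = "A", nanobody_chain: str = "H",
                  params: QualityParams | None = None) -> pd.DataFrame:
    """Score every pose of a manifest CSV against its native structure.

    The manifest needs columns model_path, native_path, complex_id,
    parent_id, refined_id. Quality columns are appended and the table is
    written to ``out_path``.
    """
    params = params or QualityParams()
    manifest = pd.read_csv(manifest_path)
    required = {"model_path", "native_path", "complex_id", "parent_id", "refined_id"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    natives: dict[str, ComplexStructure] = {}
    rows = []
    for rec in manifest.itertuples(index=False):
        if rec.native_path not in natives:
            natives[rec.native_path] = read_complex(rec.native_path, antigen_chain, nanobody_chain)
        model = read_complex(rec.model_path, antigen_chain, nanobody_chain)
        q = evaluate_pose(model, natives[rec.native_path], params)
        rows.append({"fnat": q.fnat, "irms": q.irms, "lrms": q.lrms,
                     "dockq": q.dockq, "capri": q.capri, "label": q.label})
    out = pd.concat([manifest.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    out.to_csv(Path(out_path), index=False)
    return out
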