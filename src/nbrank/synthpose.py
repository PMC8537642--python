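"""Synthetic Nb-Ag complexes and rigid-body decoy poses.

Stands in for the docking/refinement stages of the real pipeline so the
whole learn-and-rerank path can be exercised without external programs.
Each native complex is a pair of idealised helical mini-chains placed in
contact; the nanobody sequence carries the conserved anchor motifs (two
framework cysteines and a W-G-x-G J-segment) so CDR annotation recovers
the planted spans. Parent decoys are seeded rigid-body perturbations of
the nanobody spanning all DockQ bands; refined children are small
secondary perturbations of their parent. Ground-truth quality comes from
the quality module itself, so manifest labels are self-consistent by
construction.

Decoys are rigid-body only: that spans every DockQ class without any
backbone flexibility, which the feature set never sees anyway.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from nbrank.structio import Atom, ComplexStructure, Residue, chain_sequence, write_complex
from nbrank.interface import (
    CDRAnnotation,
    InterfaceDefinition,
    annotate_cdrs,
    contact_features,
    detect_interface,
)
from nbrank.quality import QualityParams, evaluate_pose, native_contacts
from nbrank.featset import (
    EnergyFeatures,
    FeatureSchema,
    FOLDX_TERMS,
    PoseRecord,
    ROSETTA_TERMS,
    assemble_features,
    load_descriptor_table,
    property_profile,
)

__all__ = [
    "SyntheticConfig",
    "GenerationError",
    "make_native",
    "make_decoys",
    "generate_dataset",
    "plant_signal",
]

# residues allowed outside the planted anchors: no C (would create spurious
# cysteine anchors) and no W (could create spurious W-G-x-G matches)
_FRAMEWORK_POOL = np.array(list("ADEFGHIKLMNPQRSTVY"))


class GenerationError(RuntimeError):
    """A requested DockQ band stayed empty after the retry cap."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world of the generator; all fields have deliberate defaults.

    Perturbation scales are paired (translation A, rotation deg) and cycle
    across parents, spanning near-native through fully dissociated poses.
    ``band_margin`` keeps generated poses away from the 0.23 label boundary
    so that PDB round-trips (1e-3 A precision) cannot flip a label.
    """

    n_complexes: int = 12
    parents_per_complex: int = 8
    refined_per_parent: int = 4
    translation_scales: tuple[float, ...] = (0.5, 1.5, 3.0, 6.0, 12.0, 24.0)
    rotation_scales: tuple[float, ...] = (3.0, 8.0, 15.0, 30.0, 60.0, 120.0)
    refine_translation: float = 0.3
    refine_rotation: float = 2.0
    nanobody_length: int = 118
    antigen_length: int = 45
    seed: int = 0
    emit_energy: bool = False
    band_margin: float = 0.02
    max_retries: int = 40

    def __post_init__(self):
        if min(self.n_complexes, self.parents_per_complex, self.refined_per_parent) < 1:
            raise ValueError("all counts must be >= 1")
        if len(self.translation_scales) != len(self.rotation_scales):
            raise ValueError("translation and rotation scale lists must pair up")
        if min(self.translation_scales) <= 0 or min(self.rotation_scales) <= 0:
            raise ValueError("perturbation scales must be positive")


# ---------------------------------------------------------------------------
# native construction


def _helix_backbone(n_res: int, rise: float = 1.5, twist_deg: float = 100.0, radius: float = 2.3) -> np.ndarray:
    """CA trace of an ideal alpha helix along +z, one row per residue."""
    k = np.arange(n_res)
    theta = np.deg2rad(twist_deg) * k
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * k])


def _residue_atoms(ca: np.ndarray, axis_xy: np.ndarray, has_cb: bool) -> list[Atom]:
    """Rigid local atom set around one CA; CB points radially outward."""
    outward = np.array([ca[0], ca[1], 0.0])
    nrm = np.linalg.norm(outward[:2])
    outward = outward / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
    atoms = [
        Atom("N", "N", ca + np.array([-0.5, 0.8, -1.0])),
        Atom("CA", "C", ca),
        Atom("C", "C", ca + np.array([0.6, -0.7, 1.0])),
        Atom("O", "O", ca + np.array([1.4, -1.2, 1.0])),
    ]
    if has_cb:
        atoms.append(Atom("CB", "C", ca + 1.53 * outward))
    return atoms


def _build_chain(sequence: str, chain_id: str, offset: np.ndarray) -> list[Residue]:
    cas = _helix_backbone(len(sequence)) + offset
    residues = []
    for i, (aa, ca) in enumerate(zip(sequence, cas)):
        name3 = _ONE_TO_THREE[aa]
        residues.append(
            Residue(chain_id, i + 1, "", name3, _residue_atoms(ca, ca, has_cb=aa != "G"))
        )
    return residues


_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _nanobody_sequence(rng: np.random.Generator, length: int) -> tuple[str, dict]:
    """Random VHH-like sequence with planted anchors and its true CDR spans."""
    seq = list(rng.choice(_FRAMEWORK_POOL, size=length))
    cys1, cys2 = 21, 91
    seq[cys1] = "C"
    seq[cys2] = "C"
    w = 104  # start of the W-G-x-G J-anchor
    seq[w], seq[w + 1], seq[w + 2], seq[w + 3] = "W", "G", "Q", "G"
    spans = {
        "cdr1": [cys1 + 4, cys1 + 11],
        "cdr2": [cys1 + 30, cys1 + 35],
        "cdr3": [cys2 + 3, w],
    }
    return "".join(seq), spans


def make_native(config: SyntheticConfig, complex_index: int) -> tuple[ComplexStructure, dict]:
    """Build one native two-chain complex with >= 5 cross-chain contacts.

    The antigen helix is slid toward the nanobody along x (centred on the
    CDR3 segment in z) until at least five residue contacts exist at 5 A
    with no steric collapse. Fully deterministic for a given config + index.
    """
    rng = np.random.default_rng([config.seed % (2**31), complex_index])
    nb_seq, spans = _nanobody_sequence(rng, config.nanobody_length)
    ag_seq = "".join(rng.choice(_FRAMEWORK_POOL, size=config.antigen_length))
    nanobody = _build_chain(nb_seq, "H", offset=np.zeros(3))
    cdr3_mid_z = 1.5 * (spans["cdr3"][0] + spans["cdr3"][1]) / 2.0
    ag_z0 = cdr3_mid_z - 1.5 * config.antigen_length / 2.0
    for dx in np.arange(14.0, 4.0, -0.25):
        antigen = _build_chain(ag_seq, "A", offset=np.array([dx, 0.0, ag_z0]))
        complex_ = ComplexStructure(antigen=antigen, nanobody=nanobody)
        contacts = native_contacts(complex_, cutoff=5.0)
        if len(contacts) >= 5:
            ag_xyz = complex_.chain_coords("antigen")
            nb_xyz = complex_.chain_coords("nanobody")
            dmin = np.min(
                np.linalg.norm(ag_xyz[:, None, :] - nb_xyz[None, :, :], axis=-1)
            )
            if dmin >= 2.6:
                return complex_, spans
    raise GenerationError("could not place chains in contact")  # pragma: no cover


# ---------------------------------------------------------------------------
# rigid-body decoys


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.2, 1.0) * max_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _perturb_nanobody(native: ComplexStructure, rng: np.random.Generator,
                      t_scale: float, r_scale: float) -> ComplexStructure:
    """Rigid rotation about the nanobody centroid plus a random translation."""
    R = _random_rotation(rng, r_scale)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = direction * rng.uniform(0.5, 1.0) * t_scale
    centroid = native.chain_coords("nanobody").mean(axis=0)
    moved = []
    for res in native.nanobody:
        atoms = [
            Atom(a.name, a.element, (R @ (a.xyz - centroid)) + centroid + t)
            for a in res.atoms
        ]
        moved.append(Residue(res.chain_id, res.resseq, res.icode, res.name3, atoms))
    return ComplexStructure(antigen=native.antigen, nanobody=moved)


def _sample_pose(native, rng, t_scale, r_scale, margin, max_retries, params):
    """Draw a perturbed pose whose DockQ keeps clear of the label boundary."""
    for _ in range(max_retries):
        pose = _perturb_nanobody(native, rng, t_scale, r_scale)
        q = evaluate_pose(pose, native, params)
        if abs(q.dockq - params.native_threshold) >= margin:
            return pose, q
    raise GenerationError("pose kept landing on the label boundary")


def _pseudo_energy(dockq: float, rng: np.random.Generator) -> EnergyFeatures:
    """Deterministic pseudo-energies: linear in DockQ plus seeded noise.

    These exercise the full 248-column path; they are synthetic fixtures,
    not physics.
    """
    feats = EnergyFeatures()
    for i, t in enumerate(ROSETTA_TERMS):
        coef = ((i % 7) - 3) * 4.0
        feats.rosetta[t] = coef * dockq + 0.5 * rng.normal()
    for i, t in enumerate(FOLDX_TERMS):
        coef = ((i % 5) - 2) * 3.0
        feats.foldx[t] = coef * dockq + 0.5 * rng.normal()
    return feats


def _featurize(pose: ComplexStructure, cdrs: CDRAnnotation, schema: FeatureSchema,
               table, energy: EnergyFeatures | None) -> np.ndarray:
    iface = detect_interface(pose, InterfaceDefinition())
    contact = contact_features(iface, cdrs, pose)
    pp = property_profile([pose.nanobody[i] for i in sorted(iface.paratope)], table)
    pe = property_profile([pose.antigen[i] for i in sorted(iface.epitope)], table)
    return assemble_features(contact, energy, pp, pe, schema)


def make_decoys(
    native: ComplexStructure,
    spans: dict,
    config: SyntheticConfig,
    complex_id: str,
    schema: FeatureSchema,
    out_dir: Path | None = None,
    descriptor_table=None,
) -> tuple[list[PoseRecord], pd.DataFrame, dict]:
    """Parent decoys across all perturbation scales plus refined children.

    Guarantees at least one native-like and one non-native-like parent per
    complex (resampling at shrunken/grown scales up to the retry cap).
    Returns (refined PoseRecords, manifest rows, parent nativeness flags).
    """
    params = QualityParams()
    table = descriptor_table or load_descriptor_table()
    cdrs = annotate_cdrs(chain_sequence(native.nanobody), user_spans=spans)
    rng = np.random.default_rng(
        [config.seed % (2**31), zlib.crc32(complex_id.encode()) % (2**31)]
    )
    scales = list(zip(config.translation_scales, config.rotation_scales))

    parents = []  # (parent_id, pose, quality)
    for p in range(config.parents_per_complex):
        t_scale, r_scale = scales[p % len(scales)]
        pose, q = _sample_pose(native, rng, t_scale, r_scale, config.band_margin,
                               config.max_retries, params)
        parents.append([f"p{p:03d}", pose, q])

    # enforce both bands among parents
    for _ in range(config.max_retries):
        if any(p[2].label == 1 for p in parents):
            break
        t, r = scales[0]
        pose, q = _sample_pose(native, rng, t / 2.0, r / 2.0, config.band_margin,
                               config.max_retries, params)
        parents[0][1:] = [pose, q]
        scales[0] = (t / 2.0, r / 2.0)
    for _ in range(config.max_retries):
        if any(p[2].label == 0 for p in parents):
            break
        t, r = scales[-1]
        pose, q = _sample_pose(native, rng, t * 2.0, r * 2.0, config.band_margin,
                               config.max_retries, params)
        parents[-1][1:] = [pose, q]
        scales[-1] = (t * 2.0, r * 2.0)
    if not (any(p[2].label == 1 for p in parents) and any(p[2].label == 0 for p in parents)):
        raise GenerationError(f"{complex_id}: could not populate both DockQ bands")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_complex(native, out_dir / f"{complex_id}_native.pdb")

    records: list[PoseRecord] = []
    manifest_rows = []
    parent_native: dict[tuple[str, str, str], bool] = {}
    for parent_id, parent_pose, parent_q in parents:
        parent_native[(complex_id, "default", parent_id)] = parent_q.label == 1
        if out_dir is not None:
            write_complex(parent_pose, out_dir / f"{complex_id}_{parent_id}.pdb")
        for c in range(config.refined_per_parent):
            child_pose, child_q = _refine_child(parent_pose, native, rng, config, params)
            refined_id = f"{parent_id}_r{c:02d}"
            energy = _pseudo_energy(child_q.dockq, rng) if config.emit_energy else None
            feats = _featurize(child_pose, cdrs, schema, table, energy)
            records.append(
                PoseRecord(
                    complex_id=complex_id,
                    docking_mode="default",
                    parent_id=parent_id,
                    refined_id=refined_id,
                    features=feats,
                    dockq=child_q.dockq,
                    label=child_q.label,
                )
            )
            manifest_rows.append(
                {
                    "complex_id": complex_id,
                    "docking_mode": "default",
                    "parent_id": parent_id,
                    "refined_id": refined_id,
                    "parent_dockq": parent_q.dockq,
                    "parent_label": parent_q.label,
                    "dockq": child_q.dockq,
                    "label": child_q.label,
                }
            )
            if out_dir is not None:
                write_complex(child_pose, out_dir / f"{complex_id}_{refined_id}.pdb")
    manifest = pd.DataFrame(manifest_rows)
    return records, manifest, parent_native


def _refine_child(parent_pose, native, rng, config, params):
    """One refined child: a small rigid perturbation of its parent,
    scored against the native and kept off the label boundary."""
    for _ in range(config.max_retries):
        child = _perturb_nanobody(parent_pose, rng, config.refine_translation,
                                  config.refine_rotation)
        q = evaluate_pose(child, native, params)
        if abs(q.dockq - params.native_threshold) >= config.band_margin:
            return child, q
    raise GenerationError("refined child kept landing on the label boundary")


def generate_dataset(
    config: SyntheticConfig,
    schema: FeatureSchema | None = None,
    out_dir: Path | None = None,
) -> tuple[list[PoseRecord], pd.DataFrame, dict, dict]:
    """Full synthetic dataset: every complex, its decoys, and ground truth.

    Returns (records, manifest, parent_native, ground_truth) where
    ground_truth maps complex_id -> planted CDR spans.
    """
    schema = schema or FeatureSchema(blocks=("contact", "property"))
    table = load_descriptor_table()
    all_records: list[PoseRecord] = []
    manifests = []
    parent_native: dict = {}
    truth: dict = {}
    for i in range(config.n_complexes):
        complex_id = f"cplx{i:03d}"
        native, spans = make_native(config, i)
        truth[complex_id] = spans
        recs, manifest, flags = make_decoys(
            native, spans, config, complex_id, schema, out_dir=out_dir,
            descriptor_table=table,
        )
        all_records.extend(recs)
        manifests.append(manifest)
        parent_native.update(flags)
    return all_records, pd.concat(manifests, ignore_index=True), parent_native, truth


def plant_signal(
    records: list[PoseRecord],
    strength: float,
    schema: FeatureSchema,
    feature: str = "KF4_paratope",
) -> tuple[list[PoseRecord], str]:
    """Shift one property-block feature by ``strength`` for label-1 records.

    Returns new records (inputs untouched) and the planted feature name;
    strength 0 leaves distributions identical across labels.
    """
    names = schema.column_names()
    if feature not in names:
        raise ValueError(f"{feature!r} not in schema")
    idx = names.index(feature)
    planted = []
    for r in records:
        feats = r.features.copy()
        if r.label == 1:
            feats[idx] += strength
        planted.append(replace(r, features=feats))
    return planted, feature
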