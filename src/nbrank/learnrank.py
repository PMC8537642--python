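"""Grouped splits, nativeness classifier, parent re-ranking, evaluation.

Training/test partitions are grouped by complex id: all refined poses of a
complex land on one side, since children of the same parent carry nearly
identical features and pose-level splits would leak. The classifier is a
gradient-boosted decision-tree ensemble (scikit-learn's histogram
implementation, which routes missing feature values natively) mapping the
feature profile to the binary nativeness label, with a positive-class
weight compensating the heavy imbalance between non-native and native
poses. Parents are re-ranked by the arithmetic mean of their refined
children's predicted native-like probability, descending, within one
docking run.

Attribution is exact tree-path (Saabas-style) additive attribution in raw
log-odds space: for every sample, the base value plus the per-feature
contributions reconstruct the ensemble's raw output exactly, and global
importance is the mean absolute contribution.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import average_precision_score

from nbrank.featset import FeatureSchema, PoseRecord

__all__ = [
    "DatasetSplit",
    "Hyperparams",
    "TrainedModel",
    "RankingTable",
    "EvalReport",
    "AttributionMatrix",
    "make_splits",
    "train",
    "predict",
    "rerank",
    "rank_statistics",
    "pr_auc",
    "compare_rankings",
    "attribute",
    "run_benchmark",
    "DegenerateLabelError",
]


class DegenerateLabelError(ValueError):
    """Training or evaluation input contains a single class only."""


@dataclass(frozen=True)
class DatasetSplit:
    repeat_index: int
    train_complexes: frozenset[str]
    test_complexes: frozenset[str]
    seed: int

    def __post_init__(self):
        if self.train_complexes & self.test_complexes:
            raise ValueError("train and test complex sets must be disjoint")


@dataclass(frozen=True)
class Hyperparams:
    """Boosted-tree settings; defaults are deliberate, fixed choices.

    300 trees of depth 6 at learning rate 0.1. The histogram learner has no
    row-subsampling knob, so none is exposed here.
    """

    n_estimators: int = 300
    max_depth: int = 6
    learning_rate: float = 0.1
    min_samples_leaf: int = 5
    l2_regularization: float = 0.0


def make_splits(
    complex_ids: Iterable[str],
    n_repeats: int = 5,
    train_frac: float = 0.8,
    seed: int = 0,
) -> list[DatasetSplit]:
    """Repeated seeded random 80/20 partitions of complex ids.

    Each repeat shuffles the id list independently (seed + repeat index)
    and takes the first floor(train_frac * n) ids for training.
    """
    ids = sorted(set(complex_ids))
    if len(ids) < n_repeats:
        raise ValueError(f"need at least {n_repeats} complexes, got {len(ids)}")
    n_train = int(train_frac * len(ids))
    if n_train == 0 or n_train == len(ids):
        raise ValueError("train fraction leaves one side empty")
    splits = []
    for r in range(n_repeats):
        rng = np.random.default_rng(seed + r)
        perm = list(rng.permutation(ids))
        splits.append(
            DatasetSplit(
                repeat_index=r,
                train_complexes=frozenset(perm[:n_train]),
                test_complexes=frozenset(perm[n_train:]),
                seed=seed + r,
            )
        )
    return splits


def _feature_matrix(records: Sequence[PoseRecord]) -> np.ndarray:
    return np.vstack([r.features for r in records]) if records else np.empty((0, 0))


@dataclass
class TrainedModel:
    """Fitted boosted-tree nativeness classifier with its schema fingerprint."""

    estimator: HistGradientBoostingClassifier
    schema_fingerprint: str
    hyperparams: Hyperparams
    seed: int
    positive_weight: float

    def check_schema(self, schema: FeatureSchema) -> None:
        if schema.fingerprint() != self.schema_fingerprint:
            raise ValueError("feature schema does not match the trained model")


def train(
    records: Sequence[PoseRecord],
    split: DatasetSplit,
    schema: FeatureSchema,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
    balance_classes: bool = True,
) -> TrainedModel:
    """Fit the classifier on the train-side complexes of a split.

    Positive-class weight defaults to n_negative / n_positive of the
    training records (native-like poses are rare), switchable off with
    ``balance_classes=False``. Deterministic for a fixed seed and data.
    """
    hyperparams = hyperparams or Hyperparams()
    train_recs = [r for r in records if r.complex_id in split.train_complexes]
    if not train_recs:
        raise ValueError("no training records on the train side of the split")
    y = np.array([r.label for r in train_recs], dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("training records contain a single label only")
    X = _feature_matrix(train_recs)
    if X.shape[1] != schema.n_columns:
        raise ValueError("record feature vectors do not match the schema")
    pos_weight = float((y == 0).sum() / max((y == 1).sum(), 1)) if balance_classes else 1.0
    sample_weight = np.where(y == 1, pos_weight, 1.0)
    est = HistGradientBoostingClassifier(
        max_iter=hyperparams.n_estimators,
        max_depth=hyperparams.max_depth,
        learning_rate=hyperparams.learning_rate,
        min_samples_leaf=hyperparams.min_samples_leaf,
        l2_regularization=hyperparams.l2_regularization,
        early_stopping=False,
        random_state=seed,
    )
    est.fit(X, y, sample_weight=sample_weight)
    return TrainedModel(
        estimator=est,
        schema_fingerprint=schema.fingerprint(),
        hyperparams=hyperparams,
        seed=seed,
        positive_weight=pos_weight,
    )


def predict(model: TrainedModel, records: Sequence[PoseRecord], schema: FeatureSchema) -> np.ndarray:
    """Native-like probability (class 1) per refined pose."""
    model.check_schema(schema)
    if not records:
        return np.empty(0, dtype=float)
    X = _feature_matrix(records)
    if X.shape[1] != schema.n_columns:
        raise ValueError("record feature vectors do not match the schema")
    return model.estimator.predict_proba(X)[:, 1]


@dataclass
class RankingTable:
    """Parent poses of one docking run ordered by averaged probability."""

    complex_id: str
    docking_mode: str
    table: pd.DataFrame  # parent_id, score, max_refined_prob, rank, native_like

    def __post_init__(self):
        ranks = sorted(self.table["rank"].tolist())
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be the permutation 1..n_parents")


def rerank(
    probabilities: Sequence[float],
    parent_ids: Sequence[str],
    complex_id: str = "",
    docking_mode: str = "default",
    native_flags: Mapping[str, bool] | None = None,
) -> RankingTable:
    """Re-rank parent poses by mean refined-pose probability, descending.

    Every refined pose maps to exactly one parent via ``parent_ids``
    (aligned with ``probabilities``). Ties break by the maximum refined
    probability, then by parent id — deterministic.
    """
    if len(probabilities) != len(parent_ids):
        raise ValueError("probabilities and parent_ids must align")
    if len(probabilities) == 0:
        raise ValueError("a docking run needs at least one refined pose")
    df = pd.DataFrame({"parent_id": list(parent_ids), "prob": np.asarray(probabilities, dtype=float)})
    grouped = df.groupby("parent_id")["prob"].agg(score="mean", max_refined_prob="max").reset_index()
    grouped = grouped.sort_values(
        by=["score", "max_refined_prob", "parent_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    grouped["rank"] = np.arange(1, len(grouped) + 1)
    grouped["native_like"] = [
        bool(native_flags.get(p, False)) if native_flags else False
        for p in grouped["parent_id"]
    ]
    return RankingTable(complex_id=complex_id, docking_mode=docking_mode, table=grouped)


def native_ranks(tables: Iterable[RankingTable]) -> np.ndarray:
    """Pooled ranks of native-like parents across docking runs."""
    ranks = []
    for t in tables:
        ranks.extend(t.table.loc[t.table["native_like"], "rank"].tolist())
    return np.asarray(ranks, dtype=float)


def rank_statistics(tables: Iterable[RankingTable]) -> dict[str, float]:
    """Median / 75th / 95th percentile of native-like parent ranks (pooled).

    Linear-interpolation (type-7) quantiles.
    """
    ranks = native_ranks(tables)
    if ranks.size == 0:
        raise ValueError("no native-like parents in any ranking table")
    return {
        "n_native_parents": int(ranks.size),
        "median_rank": float(np.percentile(ranks, 50)),
        "p75_rank": float(np.percentile(ranks, 75)),
        "p95_rank": float(np.percentile(ranks, 95)),
    }


def pr_auc(labels: Sequence[int], probabilities: Sequence[float]) -> float:
    """Area under the precision-recall curve (average precision)."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.size == 0 or len(np.unique(y)) < 2:
        raise DegenerateLabelError("PR-AUC requires both classes")
    return float(average_precision_score(y, p))


def compare_rankings(ranks_a: Sequence[float], ranks_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon matched-pairs signed-rank p-value.

    Zero-difference pairs are dropped; if every pair is tied the p-value is
    1.0. Exact null distribution for n <= 25 untied zero-excluded pairs,
    normal approximation with continuity correction otherwise.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired rank lists must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    ties = len(np.unique(np.abs(d))) < d.size
    if d.size <= 25 and not ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", alternative="two-sided", correction=(method == "approx"),
        method=method,
    )
    return float(res.pvalue)


@dataclass
class AttributionMatrix:
    """Per-sample, per-feature signed additive contributions (log-odds)."""

    contributions: np.ndarray  # (n_samples, n_features)
    base_value: float
    feature_names: list[str]

    def importance(self) -> pd.Series:
        """Mean absolute contribution per feature, descending."""
        imp = np.abs(self.contributions).mean(axis=0)
        return pd.Series(imp, index=self.feature_names).sort_values(ascending=False)


def _node_expected_values(nodes) -> np.ndarray:
    """Count-weighted expected leaf value at every node of one predictor tree."""
    n = len(nodes)
    val = np.zeros(n, dtype=float)
    # children have larger indices than parents, so a reverse sweep suffices
    for i in range(n - 1, -1, -1):
        if nodes[i]["is_leaf"]:
            val[i] = nodes[i]["value"]
        else:
            l, r = int(nodes[i]["left"]), int(nodes[i]["right"])
            cl, cr = float(nodes[l]["count"]), float(nodes[r]["count"])
            tot = cl + cr
            val[i] = (cl * val[l] + cr * val[r]) / tot if tot > 0 else 0.0
    return val


def attribute(model: TrainedModel, records: Sequence[PoseRecord], schema: FeatureSchema) -> AttributionMatrix:
    """Exact tree-path additive attribution of raw (log-odds) predictions.

    Walking each sample down every tree, the change in the count-weighted
    expected value at each split is credited to the split feature. The
    telescoping sum makes base + Σ contributions equal the ensemble's raw
    output exactly for every sample.
    """
    model.check_schema(schema)
    X = _feature_matrix(records)
    names = schema.column_names()
    n, p = X.shape
    contributions = np.zeros((n, p), dtype=float)
    base = float(np.ravel(model.estimator._baseline_prediction)[0])
    predictors = [stage[0] for stage in model.estimator._predictors]
    trees = [(pred.nodes, _node_expected_values(pred.nodes)) for pred in predictors]
    for nodes, val in trees:
        base += val[0]
        for s in range(n):
            i = 0
            while not nodes[i]["is_leaf"]:
                f = int(nodes[i]["feature_idx"])
                x = X[s, f]
                if np.isnan(x):
                    child = int(nodes[i]["left"]) if nodes[i]["missing_go_to_left"] else int(nodes[i]["right"])
                else:
                    child = int(nodes[i]["left"]) if x <= nodes[i]["num_threshold"] else int(nodes[i]["right"])
                contributions[s, f] += val[child] - val[i]
                i = child
    return AttributionMatrix(contributions=contributions, base_value=base, feature_names=names)


@dataclass
class EvalReport:
    """Per-repeat and pooled evaluation of the re-ranking experiment."""

    per_repeat: pd.DataFrame  # repeat, pr_auc_test, median/p75/p95 rank
    pooled: dict[str, float]
    tables: list[RankingTable] = field(default_factory=list, repr=False)


def run_benchmark(
    records: Sequence[PoseRecord],
    parent_native: Mapping[tuple[str, str, str], bool],
    schema: FeatureSchema,
    n_repeats: int = 5,
    seed: int = 0,
    hyperparams: Hyperparams | None = None,
) -> EvalReport:
    """The full repeated-partition experiment.

    For each of ``n_repeats`` seeded 80/20 complex-grouped splits: train,
    predict native-like probability for every test refined pose, average
    per parent, rank parents within each docking run, and pool the ranks of
    native-like parents (a parent is native-like iff its own quality label
    is, per ``parent_native`` keyed by (complex_id, docking_mode,
    parent_id)). PR-AUC is computed per repeat over test refined poses.
    """
    complex_ids = sorted({r.complex_id for r in records})
    splits = make_splits(complex_ids, n_repeats=n_repeats, seed=seed)
    rows = []
    all_tables: list[RankingTable] = []
    for split in splits:
        model = train(records, split, schema, hyperparams=hyperparams, seed=seed + split.repeat_index)
        test_recs = [r for r in records if r.complex_id in split.test_complexes]
        probs = predict(model, test_recs, schema)
        labels = [r.label for r in test_recs]
        try:
            auc = pr_auc(labels, probs)
        except DegenerateLabelError:
            auc = float("nan")
        runs: dict[tuple[str, str], tuple[list[float], list[str]]] = {}
        for r, p in zip(test_recs, probs):
            key = (r.complex_id, r.docking_mode)
            runs.setdefault(key, ([], []))
            runs[key][0].append(float(p))
            runs[key][1].append(r.parent_id)
        tables = []
        for (cid, mode), (ps, parents) in sorted(runs.items()):
            flags = {
                pid: parent_native.get((cid, mode, pid), False) for pid in set(parents)
            }
            tables.append(rerank(ps, parents, complex_id=cid, docking_mode=mode, native_flags=flags))
        stats_r = rank_statistics(tables)
        rows.append({"repeat": split.repeat_index, "pr_auc_test": auc, **stats_r})
        all_tables.extend(tables)
    pooled = rank_statistics(all_tables)
    return EvalReport(per_repeat=pd.DataFrame(rows), pooled=pooled, tables=all_tables)


def model_fingerprint(model: TrainedModel) -> str:
    """Stable digest of the fitted ensemble's structure (for artifacts)."""
    h = hashlib.sha256()
    h.update(model.schema_fingerprint.encode())
    for stage in model.estimator._predictors:
        h.update(stage[0].nodes.tobytes())
    return h.hexdigest()[:16]
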