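import numpy as np
import pytest

from nbrank.featset import FeatureSchema, PoseRecord
from nbrank.learnrank import (
    DegenerateLabelError,
    attribute,
    compare_rankings,
    make_splits,
    native_ranks,
    pr_auc,
    predict,
    rank_statistics,
    rerank,
    run_benchmark,
    train,
)
from oracles import exact_signed_rank_p, threshold_pr_auc

SCHEMA1 = FeatureSchema(blocks=("contact",))  # 52 columns; handy small schema


def _records(X, y, complexes):
    return [
        PoseRecord(
            complex_id=c,
            docking_mode="default",
            parent_id=f"p{i}",
            refined_id=f"r{i}",
            features=np.asarray(x, float),
            dockq=float(lbl),
            label=int(lbl),
        )
        for i, (x, lbl, c) in enumerate(zip(X, y, complexes))
    ]


def separable_records(n_per_complex=10, n_complexes=8, seed=0):
    """Linearly separable synthetic features on the 52-column schema:
    column 0 carries the class, the rest is noise."""
    rng = np.random.default_rng(seed)
    X, y, cx = [], [], []
    for c in range(n_complexes):
        for i in range(n_per_complex):
            label = (i + c) % 2
            row = rng.normal(size=52)
            row[0] = 5.0 + rng.normal() if label else -5.0 + rng.normal()
            X.append(row)
            y.append(label)
            cx.append(f"c{c}")
    return _records(X, y, cx)


class TestMakeSplits:
    def test_80_20_rounding(self):
        splits = make_splits([f"c{i}" for i in range(10)], n_repeats=5, seed=0)
        for s in splits:
            assert len(s.train_complexes) == 8
            assert len(s.test_complexes) == 2
            assert not s.train_complexes & s.test_complexes
            assert s.train_complexes | s.test_complexes == {f"c{i}" for i in range(10)}

    def test_determinism(self):
        a = make_splits([f"c{i}" for i in range(12)], seed=3)
        b = make_splits([f"c{i}" for i in range(12)], seed=3)
        assert a == b

    def test_too_few(self):
        with pytest.raises(ValueError):
            make_splits(["a", "b"], n_repeats=5)

    def test_coverage_matches_direct_simulation(self):
        # same RNG protocol run independently: per repeat, shuffle and cut
        ids = sorted(f"c{i:03d}" for i in range(100))
        splits = make_splits(ids, n_repeats=5, seed=9)
        for r, s in enumerate(splits):
            rng = np.random.default_rng(9 + r)
            perm = list(rng.permutation(ids))
            assert s.train_complexes == frozenset(perm[:80])
            assert s.test_complexes == frozenset(perm[80:])


class TestTrainPredict:
    def test_separable_data_learned(self):
        records = separable_records()
        split = make_splits({r.complex_id for r in records}, n_repeats=1, seed=0)[0]
        model = train(records, split, SCHEMA1, seed=0)
        train_recs = [r for r in records if r.complex_id in split.train_complexes]
        probs = predict(model, train_recs, SCHEMA1)
        acc = np.mean((probs > 0.5).astype(int) == [r.label for r in train_recs])
        assert acc == 1.0
        pos = [r for r in train_recs if r.label == 1]
        assert np.all(predict(model, pos, SCHEMA1) > 0.5)

    def test_single_class_rejected(self):
        records = separable_records()
        for r in records:
            r.label = 1
        split = make_splits({r.complex_id for r in records}, n_repeats=1, seed=0)[0]
        with pytest.raises(DegenerateLabelError):
            train(records, split, SCHEMA1, seed=0)

    def test_retrain_determinism(self):
        records = separable_records()
        split = make_splits({r.complex_id for r in records}, n_repeats=1, seed=1)[0]
        probe = [r for r in records if r.complex_id in split.test_complexes]
        p1 = predict(train(records, split, SCHEMA1, seed=5), probe, SCHEMA1)
        p2 = predict(train(records, split, SCHEMA1, seed=5), probe, SCHEMA1)
        np.testing.assert_array_equal(p1, p2)

    def test_missing_values_supported(self):
        records = separable_records()
        for r in records[::3]:
            r.features[10:20] = np.nan
        split = make_splits({r.complex_id for r in records}, n_repeats=1, seed=0)[0]
        model = train(records, split, SCHEMA1, seed=0)
        probs = predict(model, records, SCHEMA1)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_schema_mismatch_rejected(self):
        records = separable_records()
        split = make_splits({r.complex_id for r in records}, n_repeats=1, seed=0)[0]
        model = train(records, split, SCHEMA1, seed=0)
        with pytest.raises(ValueError):
            predict(model, records, FeatureSchema(blocks=("property",)))

    def test_empty_predict(self):
        records = separable_records()
        split = make_splits({r.complex_id for r in records}, n_repeats=1, seed=0)[0]
        model = train(records, split, SCHEMA1, seed=0)
        assert predict(model, [], SCHEMA1).size == 0


class TestRerank:
    def test_single_parent(self):
        t = rerank([0.4, 0.6], ["p1", "p1"])
        assert list(t.table["rank"]) == [1]

    def test_hand_sorted_means(self):
        probs = [0.9, 0.9, 0.2, 0.2, 0.6, 0.6]
        parents = ["P1", "P1", "P2", "P2", "P3", "P3"]
        t = rerank(probs, parents)
        assert list(t.table["parent_id"]) == ["P1", "P3", "P2"]
        assert list(t.table["rank"]) == [1, 2, 3]

    def test_mean_beats_single_high(self):
        # {0.8, 0.4} mean 0.60 vs {0.7, 0.6} mean 0.65: second parent first
        t = rerank([0.8, 0.4, 0.7, 0.6], ["A", "A", "B", "B"])
        assert list(t.table["parent_id"]) == ["B", "A"]

    def test_within_parent_order_invariance(self):
        a = rerank([0.8, 0.4, 0.7, 0.6], ["A", "A", "B", "B"])
        b = rerank([0.4, 0.8, 0.6, 0.7], ["A", "A", "B", "B"])
        assert list(a.table["parent_id"]) == list(b.table["parent_id"])

    def test_tie_broken_by_max_then_id(self):
        # equal means 0.5; A has the higher best child
        t = rerank([0.9, 0.1, 0.5, 0.5], ["A", "A", "B", "B"])
        assert list(t.table["parent_id"]) == ["A", "B"]
        # fully tied: lexicographic parent id
        t2 = rerank([0.5, 0.5], ["B", "A"])
        assert list(t2.table["parent_id"]) == ["A", "B"]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rerank([], [])


class TestRankStatistics:
    def _tables(self, ranks):
        probs = []
        parents = []
        n = max(ranks) + 2
        for i in range(n):
            probs.append(1.0 - i / n)
            parents.append(f"p{i}")
        flags = {f"p{r - 1}": True for r in ranks}
        return [rerank(probs, parents, native_flags=flags)]

    def test_all_rank_one(self):
        tables = [rerank([0.9, 0.1], ["a", "b"], native_flags={"a": True}) for _ in range(3)]
        stats = rank_statistics(tables)
        assert stats["median_rank"] == 1.0

    def test_median_of_five(self):
        tables = self._tables([1, 2, 3, 4, 5])
        assert rank_statistics(tables)["median_rank"] == 3.0

    def test_interpolated_quantiles_frozen_oracle(self):
        # ranks {2,5,1,9,4,7}: sorted [1,2,4,5,7,9]; type-7 interpolation gives
        # median 4.5, p75 = 5 + 0.75*(7-5) = 6.5, p95 = 7 + 0.75*(9-7) = 8.5
        tables = self._tables([2, 5, 1, 9, 4, 7])
        assert sorted(native_ranks(tables).tolist()) == [1, 2, 4, 5, 7, 9]
        stats = rank_statistics(tables)
        assert stats["median_rank"] == pytest.approx(4.5)
        assert stats["p75_rank"] == pytest.approx(6.5)
        assert stats["p95_rank"] == pytest.approx(8.5)
        assert stats["median_rank"] <= stats["p75_rank"] <= stats["p95_rank"]

    def test_no_native_parents_errors(self):
        with pytest.raises(ValueError):
            rank_statistics([rerank([0.5], ["a"])])


class TestPrAuc:
    def test_perfect_separation(self):
        assert pr_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        y = [1, 0, 0, 0, 1, 0, 0, 0, 0, 0]
        assert pr_auc(y, [0.5] * 10) == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_threshold_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=8)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, size=8)
        s = rng.uniform(size=8)
        assert pr_auc(y, s) == pytest.approx(threshold_pr_auc(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelError):
            pr_auc([1, 1, 1], [0.1, 0.5, 0.9])


class TestCompareRankings:
    def test_identical_lists(self):
        assert compare_rankings([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0

    def test_exact_enumeration_n6(self):
        a = [3.0, 7.0, 1.0, 10.0, 4.0, 8.0]
        b = [5.0, 6.0, 4.0, 2.0, 9.0, 8.5]
        assert compare_rankings(a, b) == pytest.approx(exact_signed_rank_p(a, b), abs=1e-9)

    def test_dominated_pairs_significant(self):
        rng = np.random.default_rng(2)
        b = rng.uniform(10, 20, size=20)
        a = b - rng.uniform(1, 3, size=20)  # a < b always
        assert compare_rankings(a, b) < 0.05

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_rankings([1, 2, 3, 4, 5], [1, 2, 3, 4])


class TestAttribute:
    def test_additivity_to_raw_output(self):
        records = separable_records()
        split = make_splits({r.complex_id for r in records}, n_repeats=1, seed=0)[0]
        model = train(records, split, SCHEMA1, seed=0)
        test_recs = [r for r in records if r.complex_id in split.test_complexes]
        attr = attribute(model, test_recs, SCHEMA1)
        X = np.vstack([r.features for r in test_recs])
        raw = model.estimator.decision_function(X)
        recon = attr.base_value + attr.contributions.sum(axis=1)
        np.testing.assert_allclose(recon, raw, atol=1e-6)

    def test_single_informative_feature_dominates(self):
        records = separable_records()
        split = make_splits({r.complex_id for r in records}, n_repeats=1, seed=0)[0]
        model = train(records, split, SCHEMA1, seed=0)
        attr = attribute(model, records, SCHEMA1)
        imp = attr.importance()
        assert imp.index[0] == SCHEMA1.column_names()[0]
        # the informative column carries the overwhelming share of attribution
        assert imp.iloc[0] > 5 * imp.iloc[1]


class TestEndToEnd:
    def test_grouped_split_no_leakage(self, small_dataset, contact_schema):
        records, _, _, _ = small_dataset
        splits = make_splits({r.complex_id for r in records}, n_repeats=3, seed=0)
        for s in splits:
            train_poses = {r.key() for r in records if r.complex_id in s.train_complexes}
            test_poses = {r.key() for r in records if r.complex_id in s.test_complexes}
            assert not train_poses & test_poses
            assert len(train_poses) + len(test_poses) == len(records)
            assert not {k[0] for k in train_poses} & {k[0] for k in test_poses}

    def test_oracle_classifier_perfect_ordering(self, small_dataset):
        records, manifest, parent_native, _ = small_dataset
        by_run = {}
        for r in records:
            by_run.setdefault((r.complex_id, r.docking_mode), ([], []))
            by_run[(r.complex_id, r.docking_mode)][0].append(float(r.label))
            by_run[(r.complex_id, r.docking_mode)][1].append(r.parent_id)
        for (cid, mode), (probs, parents) in by_run.items():
            flags = {p: parent_native[(cid, mode, p)] for p in set(parents)}
            t = rerank(probs, parents, native_flags=flags).table
            # parents whose children are all non-native score 0
            zero_parents = t.loc[t["score"] == 0.0, "rank"]
            positive_parents = t.loc[t["score"] > 0.0, "rank"]
            if len(zero_parents) and len(positive_parents):
                assert positive_parents.max() < zero_parents.min()

    def test_run_benchmark_report_shape(self, small_dataset, contact_schema):
        records, _, parent_native, _ = small_dataset
        report = run_benchmark(records, parent_native, contact_schema, n_repeats=3, seed=0)
        assert len(report.per_repeat) == 3
        pooled = report.pooled
        assert pooled["median_rank"] <= pooled["p75_rank"] <= pooled["p95_rank"]
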