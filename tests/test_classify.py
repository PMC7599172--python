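"""Training-set construction, curation, ROC machinery and the classifier."""

import numpy as np
import pandas as pd
import pytest

from tnsight.classify import (
    ContradictionRule,
    TrainingSet,
    auc_vs_min_targets,
    build_ortholog_training_set,
    contradiction_filter,
    cross_validate,
    curate_orfs,
    fit_and_predict,
    roc_and_threshold,
    roc_curve_points,
)
from tnsight.genome import Genome, ORFRecord


def mann_whitney_auc(labels, scores):
    """Pairwise-ranking AUC oracle: P(score_pos > score_neg) + 0.5 ties."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestOrthologTrainingSet:
    def _map(self, rows):
        return pd.DataFrame(rows, columns=["source_id_a", "source_id_b", "target_id"])

    def test_essential_iff_essential_in_both(self):
        la = {"a1": "essential", "a2": "essential", "a3": "essential",
              "a4": "non_essential"}
        lb = {"b1": "essential", "b2": "essential", "b3": "non_essential",
              "b4": "non_essential"}
        omap = self._map(
            [("a1", "b1", "t1"), ("a2", "b2", "t2"), ("a3", "b3", "t3"),
             ("a4", "b4", "t4")]
        )
        ts = build_ortholog_training_set(la, lb, omap)
        assert set(ts.table.index[ts.labels == "essential"]) == {"t1", "t2"}
        assert set(ts.table.index[ts.labels == "non_essential"]) == {"t4"}
        assert ts.counts["conflicting"] == 1  # t3 conflicts, excluded

    def test_ambiguous_targets_dropped(self):
        la = {"a1": "essential", "a2": "essential"}
        lb = {"b1": "essential", "b2": "essential"}
        omap = self._map([("a1", "b1", "t1"), ("a2", "b2", "t1"),
                          ("a1", "b1", "t2")])
        ts = build_ortholog_training_set(la, lb, omap)
        assert list(ts.table.index) == ["t2"]
        assert ts.counts["ambiguous_dropped"] == 2

    def test_missing_ortholog_excluded(self):
        la = {"a1": "essential"}
        lb = {}
        omap = self._map([("a1", "b1", "t1"), ("a1", "bX", "t2")])
        with pytest.raises(ValueError):
            build_ortholog_training_set(la, lb, omap)


class TestCuration:
    def test_short_orf_removed(self):
        orfs = [ORFRecord("short", "c", 0, 250, "+"),
                ORFRecord("ok", "c", 300, 700, "+")]
        rep = curate_orfs(orfs)
        assert rep.reason("short") == "length_lt_300"
        assert rep.reason("ok") == "ok"

    def test_deleted_gene_removed(self):
        orfs = [ORFRecord("leu2", "c", 0, 900, "+")]
        rep = curate_orfs(orfs, deleted_genes={"leu2"})
        assert rep.reason("leu2") == "deleted_in_strain"

    def test_exclusion_list(self):
        orfs = [ORFRecord("dub", "c", 0, 900, "+")]
        rep = curate_orfs(orfs, exclusion_list={"dub"})
        assert rep.reason("dub") == "dubious_annotation"

    def test_duplicated_region_detected_by_kmer_multiplicity(self):
        rng = np.random.default_rng(2)
        uniq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
        dup = "".join("ACGT"[i] for i in rng.integers(0, 4, size=500))
        genome = Genome({"c": uniq[:1000] + dup + uniq[1000:] + dup})
        orf_dup = ORFRecord("dup", "c", 1000, 1500, "+")
        orf_uni = ORFRecord("uni", "c", 100, 600, "+")
        rep = curate_orfs([orf_dup, orf_uni], genome=genome, kmer=30)
        assert rep.reason("dup") == "duplicated_region"
        assert rep.reason("uni") == "ok"


class TestContradictionFilter:
    def _features(self, ni, fi, n_window):
        return pd.DataFrame(
            {"neighborhood_index": ni, "freedom_index": fi, "n_window": n_window},
            index=pd.Index([f"g{i}" for i in range(len(ni))], name="orf_id"),
        )

    def test_rule_fires_on_contradicted_essential(self):
        feats = self._features([1.2, 0.0, 1.3], [0.1, 1.0, 0.1], [50, 50, 50])
        ts = TrainingSet.from_labels(
            {"g0": "essential", "g1": "essential", "g2": "non_essential"}
        )
        out = contradiction_filter(ts, feats, ContradictionRule(ni_min=1.0))
        assert "g0" not in out.table.index          # contradicted, removed
        assert "g1" in out.table.index              # zero insertions, kept
        assert "g2" in out.table.index              # non-essential never removed
        assert out.removed.loc["g0", "reason"] == "contradicts_label"

    def test_sparse_neighborhood_protected(self):
        feats = self._features([1.2], [0.1], [5])
        ts = TrainingSet.from_labels({"g0": "essential"})
        out = contradiction_filter(ts, feats, ContradictionRule(ni_min=1.0))
        assert "g0" in out.table.index


class TestROC:
    def test_curve_matches_constructed_points(self):
        # 8 pos + 1 neg at .9 -> (0.1, 0.8); +1 pos +2 neg at .5 -> (0.3, 0.9)
        labels = [1] * 8 + [0] + [1] + [0] * 2 + [1] + [0] * 7
        scores = [0.9] * 9 + [0.5] * 3 + [0.1] * 8
        curve, choice = roc_and_threshold(np.array(labels), np.array(scores))
        pts = list(zip(curve.fpr.round(6), curve.tpr.round(6)))
        assert pts == [(0.0, 0.0), (0.1, 0.8), (0.3, 0.9), (1.0, 1.0)]
        assert choice.statistic == pytest.approx(0.7)
        assert (choice.fpr, choice.tpr) == (0.1, 0.8)

    def test_perfect_classifier(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        curve, choice = roc_and_threshold(labels, scores)
        assert curve.auc == 1.0
        assert choice.statistic == pytest.approx(1.0)

    def test_trapezoid_equals_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(60):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            scores = rng.choice(np.linspace(0, 1, 11), size=n)
            if np.all(scores == scores[0]):
                continue
            curve = roc_curve_points(labels, scores)
            assert curve.auc == pytest.approx(mann_whitney_auc(labels, scores))

    def test_youden_equals_brute_force(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            n = int(rng.integers(6, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            scores = rng.random(n).round(2)
            if np.all(scores == scores[0]):
                continue
            curve, choice = roc_and_threshold(labels, scores, "youden")
            best = -np.inf
            for t in np.unique(scores):
                pred = scores >= t
                tpr = (pred & (labels == 1)).sum() / (labels == 1).sum()
                fpr = (pred & (labels == 0)).sum() / (labels == 0).sum()
                best = max(best, tpr - fpr)
            assert choice.statistic == pytest.approx(max(best, 0.0))

    def test_auc_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(77)
        for _ in range(25):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            scores = rng.random(n)
            assert roc_curve_points(labels, scores).auc == pytest.approx(
                roc_auc_score(labels, scores)
            )

    def test_euclidean_close_to_youden_on_smooth_curve(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(0.7, 0.15, 200), rng.normal(0.3, 0.15, 200)]
        labels = np.r_[np.ones(200, int), np.zeros(200, int)]
        _, youden = roc_and_threshold(labels, scores, "youden")
        _, eucl = roc_and_threshold(labels, scores, "euclidean")
        assert abs(youden.threshold - eucl.threshold) < 0.2

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            roc_curve_points(np.array([1, 1]), np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            roc_curve_points(np.array([1, 0]), np.array([0.5, 0.5]))


def _separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"g{i}" for i in range(n)]
    ess = ids[: n // 3]
    feats = pd.DataFrame(
        {
            "insertions": [0] * len(ess) + list(rng.integers(20, 60, n - len(ess))),
            "reads": rng.integers(0, 100, n),
            "freedom_index": [1.0] * len(ess)
            + list(rng.uniform(0.05, 0.3, n - len(ess))),
        },
        index=pd.Index(ids, name="orf_id"),
    )
    labels = {g: ("essential" if g in ess else "non_essential") for g in ids}
    return feats, TrainingSet.from_labels(labels)


class TestCrossValidate:
    def test_separable_data_perfect_auc(self):
        feats, ts = _separable()
        cv = cross_validate(feats, ts, n_trees=50)
        assert cv["auc_mean"] == 1.0

    def test_permuted_labels_near_chance(self):
        feats, ts = _separable(n=80, seed=1)
        rng = np.random.default_rng(0)
        aucs = []
        for rep in range(10):
            perm = rng.permutation(ts.table["label"].to_numpy())
            permuted = TrainingSet.from_labels(
                dict(zip(ts.table.index, perm))
            )
            aucs.append(cross_validate(feats, permuted, n_trees=25,
                                       seed=rep)["auc_mean"])
        assert 0.35 < np.mean(aucs) < 0.65

    def test_deterministic_given_seed(self):
        feats, ts = _separable(seed=3)
        a = cross_validate(feats, ts, n_trees=30, seed=0)
        b = cross_validate(feats, ts, n_trees=30, seed=0)
        assert np.array_equal(a["oof_scores"], b["oof_scores"])

    def test_single_class_raises(self):
        feats, _ = _separable()
        ts = TrainingSet.from_labels({g: "essential" for g in feats.index[:10]})
        with pytest.raises(ValueError):
            cross_validate(feats, ts)


class TestFitAndPredict:
    def test_training_genes_called_consistently(self):
        feats, ts = _separable()
        verdicts, _ = fit_and_predict(feats, ts, threshold=0.5, n_trees=50)
        called = verdicts.table.loc[ts.table.index, "verdict"]
        assert (called == ts.table["label"]).all()

    def test_importances_normalized(self):
        feats, ts = _separable()
        _, imp = fit_and_predict(feats, ts, threshold=0.5, n_trees=50)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_excluded_orfs_stay_excluded(self):
        feats, ts = _separable()
        orfs = [ORFRecord(g, "c", 0, 250, "+") for g in feats.index[:2]] + [
            ORFRecord(g, "c", 300, 900, "+") for g in feats.index[2:]
        ]
        rep = curate_orfs(orfs)
        verdicts, _ = fit_and_predict(feats, ts, 0.5, curation=rep, n_trees=20)
        assert (verdicts.table.iloc[:2]["verdict"] == "excluded").all()
        assert (verdicts.table.iloc[:2]["reason"] == "length_lt_300").all()


class TestAucVsMinTargets:
    def test_gene_count_non_increasing_and_baseline(self):
        feats, ts = _separable(n=90, seed=5)
        rng = np.random.default_rng(6)
        targets = {g: int(t) for g, t in zip(feats.index, rng.integers(0, 12, 90))}
        sweep = auc_vs_min_targets(feats, ts, targets, cutoffs=range(0, 6),
                                   n_trees=25)
        assert sweep["n_genes"].is_monotonic_decreasing
        full = cross_validate(feats, ts, n_trees=25)["auc_mean"]
        assert sweep.loc[sweep["min_targets"] == 0, "auc"].iloc[0] == pytest.approx(full)
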