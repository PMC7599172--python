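"""Essentiality classification: training-set construction and curation,
Random-Forest cross-validation, ROC threshold selection, and per-ORF
verdicts.

The ROC sweep, trapezoidal AUC and Youden/Euclidean threshold optima are
implemented from their definitions (they are part of the method, not just
plumbing); scikit-learn provides the forest itself and serves as an
independent cross-check of the ROC machinery in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .features import feature_columns
from .genome import Genome, ORFRecord

ESSENTIAL = "essential"
NON_ESSENTIAL = "non_essential"


@dataclass
class TrainingSet:
    """Binary essentiality labels with per-gene provenance.

    ``table`` columns: label in {essential, non_essential}, provenance.
    Genes removed by curation/filtering stay in ``removed`` with a reason.
    """

    table: pd.DataFrame
    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["label", "reason"])
    )
    counts: dict = field(default_factory=dict)

    @classmethod
    def from_labels(
        cls, labels: Mapping[str, str], provenance: str = "native"
    ) -> "TrainingSet":
        df = pd.DataFrame(
            {"label": pd.Series(dict(labels)), "provenance": provenance}
        )
        bad = set(df["label"]) - {ESSENTIAL, NON_ESSENTIAL}
        if bad:
            raise ValueError(f"labels must be binary; got extras {sorted(bad)}")
        df.index.name = "orf_id"
        return cls(df)

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def binary(self) -> pd.Series:
        """1 = essential (positive class), 0 = non-essential."""
        return (self.table["label"] == ESSENTIAL).astype(int)

    def __len__(self) -> int:
        return len(self.table)


def read_labels_csv(path) -> TrainingSet:
    df = pd.read_csv(path)
    return TrainingSet.from_labels(dict(zip(df["orf_id"], df["label"])))


def build_ortholog_training_set(
    labels_a: Mapping[str, str],
    labels_b: Mapping[str, str],
    ortholog_map: pd.DataFrame,
    target_orfs: Sequence[str] | None = None,
) -> TrainingSet:
    """Label target-species genes from two source species' deletion data.

    A target gene is essential iff its orthologs in BOTH sources are
    essential; non-essential iff both are non-essential; anything else
    (conflict, missing ortholog, ambiguous many-to-many mapping) is
    excluded. ``ortholog_map`` columns: source_id_a, source_id_b, target_id.
    """
    required = {"source_id_a", "source_id_b", "target_id"}
    if not required <= set(ortholog_map.columns):
        raise ValueError(f"ortholog map needs columns {sorted(required)}")
    dup = ortholog_map["target_id"].duplicated(keep=False)
    n_ambiguous = int(dup.sum())
    mapped = ortholog_map[~dup]
    labels: dict[str, str] = {}
    n_conflict = 0
    n_missing = 0
    universe = set(target_orfs) if target_orfs is not None else None
    for row in mapped.itertuples(index=False):
        if universe is not None and row.target_id not in universe:
            continue
        la = labels_a.get(row.source_id_a)
        lb = labels_b.get(row.source_id_b)
        if la is None or lb is None:
            n_missing += 1
            continue
        if la == lb:
            labels[row.target_id] = la
        else:
            n_conflict += 1
    if not labels:
        raise ValueError("ortholog transfer produced an empty training set")
    ts = TrainingSet.from_labels(labels, provenance="ortholog_transfer")
    ts.counts = {
        "essential": int((ts.labels == ESSENTIAL).sum()),
        "non_essential": int((ts.labels == NON_ESSENTIAL).sum()),
        "conflicting": n_conflict,
        "missing": n_missing,
        "ambiguous_dropped": n_ambiguous,
    }
    return ts


# ---------------------------------------------------------------------------
# curation


@dataclass
class CurationReport:
    """Per-ORF keep/remove decisions, one primary reason each."""

    table: pd.DataFrame  # index orf_id; columns kept(bool), reason

    @property
    def kept_ids(self) -> set[str]:
        return set(self.table.index[self.table["kept"]])

    @property
    def removed_ids(self) -> set[str]:
        return set(self.table.index[~self.table["kept"]])

    def reason(self, orf_id: str) -> str:
        return self.table.loc[orf_id, "reason"]


def _duplicated_fraction(
    orf: ORFRecord, genome: Genome, kmer_counts: dict, k: int
) -> float:
    seq = genome.sequences[orf.chrom][orf.start : orf.end]
    if len(seq) < k:
        return 0.0
    from .genome import reverse_complement

    n_multi = 0
    n_total = len(seq) - k + 1
    for i in range(n_total):
        kmer = seq[i : i + k]
        occ = kmer_counts.get(kmer, 0) + kmer_counts.get(reverse_complement(kmer), 0)
        if occ > 1:
            n_multi += 1
    return n_multi / n_total


def genome_kmer_counts(genome: Genome, k: int = 75) -> dict:
    """Forward-strand k-mer occurrence counts over the whole genome."""
    counts: dict[str, int] = {}
    for seq in genome.sequences.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def curate_orfs(
    orfs: Sequence[ORFRecord],
    genome: Genome | None = None,
    deleted_genes: set[str] | None = None,
    exclusion_list: set[str] | None = None,
    min_length: int = 300,
    kmer: int = 75,
    dup_fraction_cutoff: float = 0.5,
    kmer_counts: dict | None = None,
) -> CurationReport:
    """Remove ORFs a short-read insertion assay cannot score reliably.

    Removal reasons, applied in order: (1) duplicated_region — the fraction
    of read-length k-mers in the ORF occurring more than once in the genome
    exceeds the cutoff (multi-mapping reads are discarded upstream, so such
    genes look falsely insertion-free), or membership in a user exclusion
    list (dubious_annotation); (2) length_lt_300 — short ORFs have too low
    an insertion probability; (3) deleted_in_strain — genes absent from the
    mutagenized strains cannot acquire insertions.
    """
    deleted_genes = deleted_genes or set()
    exclusion_list = exclusion_list or set()
    if genome is not None and kmer_counts is None:
        kmer_counts = genome_kmer_counts(genome, kmer)
    rows = {}
    for orf in orfs:
        reason = "ok"
        if genome is not None and _duplicated_fraction(
            orf, genome, kmer_counts, kmer
        ) > dup_fraction_cutoff:
            reason = "duplicated_region"
        elif orf.orf_id in exclusion_list:
            reason = "dubious_annotation"
        elif orf.length < min_length:
            reason = "length_lt_300"
        elif orf.orf_id in deleted_genes:
            reason = "deleted_in_strain"
        rows[orf.orf_id] = {"kept": reason == "ok", "reason": reason}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "orf_id"
    return CurationReport(df)


@dataclass
class ContradictionRule:
    """Rule-based surrogate for visual screening of ortholog-derived labels.

    An essential-labeled gene whose ORF is freely hit (high NI, low FI) in a
    data-rich neighborhood contradicts its label and is dropped. ``ni_min``
    of None means "the median NI of non-essential-labeled genes".
    """

    ni_min: float | None = None
    fi_max: float = 0.25
    min_window_hits: int = 20


def contradiction_filter(
    training: TrainingSet,
    features: pd.DataFrame,
    rule: ContradictionRule | None = None,
) -> TrainingSet:
    """Drop essential-labeled genes whose insertion pattern contradicts the
    label. Non-essential labels are never touched."""
    rule = rule or ContradictionRule()
    common = training.table.index.intersection(features.index)
    feats = features.loc[common]
    labels = training.table.loc[common]
    ni_min = rule.ni_min
    if ni_min is None:
        non_ess = feats.loc[labels["label"] == NON_ESSENTIAL, "neighborhood_index"]
        ni_min = float(non_ess.median()) if len(non_ess) else 1.0
    contradicted = (
        (labels["label"] == ESSENTIAL)
        & (feats["neighborhood_index"] >= ni_min)
        & (feats["freedom_index"] < rule.fi_max)
        & (feats["n_window"] >= rule.min_window_hits)
    )
    removed = labels[contradicted].copy()
    removed["reason"] = "contradicts_label"
    kept = training.table.drop(index=removed.index)
    out = TrainingSet(kept, removed=removed[["label", "reason"]])
    out.counts = dict(training.counts, contradiction_removed=int(contradicted.sum()))
    return out


# ---------------------------------------------------------------------------
# ROC / threshold


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class ThresholdChoice:
    method: str
    threshold: float
    statistic: float  # J for youden; distance to (0,1) for euclidean
    fpr: float
    tpr: float


def roc_curve_points(labels: np.ndarray, scores: np.ndarray) -> ROCCurve:
    """ROC sweep over all distinct score thresholds (predict essential when
    score >= threshold), with trapezoidal AUC."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    if np.all(scores == scores[0]):
        raise ValueError("constant scores give a degenerate ROC curve")
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # cumulative counts at each distinct threshold (score >= t)
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = np.cumsum(1 - sorted_labels)[distinct]
    thresholds = sorted_scores[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, thresholds]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def roc_and_threshold(
    labels: np.ndarray, scores: np.ndarray, method: str = "youden"
) -> tuple[ROCCurve, ThresholdChoice]:
    """ROC curve plus the operating threshold.

    Youden: maximize J = TPR - FPR (vertical distance above the chance
    diagonal). Euclidean: minimize distance to the perfect corner (0, 1) —
    computed as the sanity alternative. Ties break toward lower FPR.
    """
    curve = roc_curve_points(labels, scores)
    j = curve.tpr - curve.fpr
    dist = np.sqrt((1.0 - curve.tpr) ** 2 + curve.fpr**2)
    if method == "youden":
        crit = j
        best = _argbest(crit, curve.fpr, maximize=True)
        stat = float(j[best])
    elif method == "euclidean":
        crit = dist
        best = _argbest(crit, curve.fpr, maximize=False)
        stat = float(dist[best])
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    choice = ThresholdChoice(
        method=method,
        threshold=float(curve.thresholds[best]),
        statistic=stat,
        fpr=float(curve.fpr[best]),
        tpr=float(curve.tpr[best]),
    )
    return curve, choice


def _argbest(crit: np.ndarray, fpr: np.ndarray, maximize: bool) -> int:
    best_val = crit.max() if maximize else crit.min()
    idx = np.flatnonzero(crit == best_val)
    return int(idx[np.argmin(fpr[idx])])


# ---------------------------------------------------------------------------
# cross-validation / final model


def _make_forest(n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=n_trees, random_state=seed)


def cross_validate(
    features: pd.DataFrame,
    training: TrainingSet,
    k: int = 5,
    n_trees: int = 200,
    seed: int = 0,
) -> dict:
    """Stratified k-fold CV; returns out-of-fold probabilities and AUCs.

    Deterministic given the seed (fold shuffling and forest share it).
    """
    cols = feature_columns(features)
    common = training.table.index.intersection(features.index)
    X = features.loc[common, cols].to_numpy(dtype=float)
    y = training.binary().loc[common].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes in the training set")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    fold_aucs = []
    for train_idx, test_idx in skf.split(X, y):
        clf = _make_forest(n_trees, seed)
        clf.fit(X[train_idx], y[train_idx])
        p = clf.predict_proba(X[test_idx])[:, 1]
        oof[test_idx] = p
        fold_aucs.append(roc_curve_points(y[test_idx], p).auc)
    return {
        "orf_ids": list(common),
        "oof_scores": oof,
        "labels": y,
        "auc_folds": [float(a) for a in fold_aucs],
        "auc_mean": float(np.mean(fold_aucs)),
    }


@dataclass
class VerdictTable:
    """Per-ORF essentiality probability, binary verdict and curation flag."""

    table: pd.DataFrame  # index orf_id; probability, verdict, reason
    threshold: float

    def essential_ids(self) -> set[str]:
        return set(self.table.index[self.table["verdict"] == ESSENTIAL])

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def fit_and_predict(
    features: pd.DataFrame,
    training: TrainingSet,
    threshold: float,
    curation: CurationReport | None = None,
    n_trees: int = 200,
    seed: int = 0,
) -> tuple[VerdictTable, pd.Series]:
    """Fit the final forest on the full training set and call every ORF.

    Curated-out ORFs get verdict "excluded" with their removal reason,
    whatever their probability. Returns the verdicts and impurity-based
    feature importances (normalized to sum to 1).
    """
    cols = feature_columns(features)
    common = training.table.index.intersection(features.index)
    if len(common) < len(training.table):
        missing = set(training.table.index) - set(common)
        raise ValueError(f"training genes missing from features: {sorted(missing)[:5]}")
    clf = _make_forest(n_trees, seed)
    clf.fit(
        features.loc[common, cols].to_numpy(dtype=float),
        training.binary().loc[common].to_numpy(),
    )
    prob = clf.predict_proba(features[cols].to_numpy(dtype=float))[:, 1]
    verdict = np.where(prob >= threshold, ESSENTIAL, NON_ESSENTIAL)
    reason = np.array(["ok"] * len(features), dtype=object)
    if curation is not None:
        excluded = features.index.isin(curation.removed_ids)
        verdict = np.where(excluded, "excluded", verdict)
        reason[excluded] = [
            curation.reason(i) for i in features.index[excluded]
        ]
    table = pd.DataFrame(
        {"probability": prob, "verdict": verdict, "reason": reason},
        index=features.index,
    )
    importances = pd.Series(clf.feature_importances_, index=cols)
    importances = importances / importances.sum()
    return VerdictTable(table, threshold), importances


def auc_vs_min_targets(
    features: pd.DataFrame,
    training: TrainingSet,
    target_counts: Mapping[str, int],
    cutoffs: Sequence[int] = range(0, 11),
    k: int = 5,
    n_trees: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """CV AUC when training only on genes with >= cutoff target sequences.

    Quantifies how much a sparse target motif (e.g. TTAA) limits resolution:
    genes with few targets cannot accumulate insertions even when fully
    dispensable. Cutoffs leaving a single class are skipped with a warning.
    """
    rows = []
    tc = pd.Series(dict(target_counts))
    for cutoff in cutoffs:
        keep = tc[tc >= cutoff].index.intersection(training.table.index)
        sub = TrainingSet(training.table.loc[keep])
        labels = sub.binary()
        if labels.nunique() < 2:
            warnings.warn(f"cutoff {cutoff}: single-class training set, skipped")
            continue
        cv = cross_validate(features, sub, k=k, n_trees=n_trees, seed=seed)
        rows.append(
            {"min_targets": int(cutoff), "auc": cv["auc_mean"], "n_genes": len(keep)}
        )
    return pd.DataFrame(rows)
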