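"""Cross-study analyses: transfer-learning AUC grid, feature-importance
correlations, verdict agreement against reference labels, and
haploid-vs-diploid comparison."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .classify import (
    ESSENTIAL,
    NON_ESSENTIAL,
    CurationReport,
    TrainingSet,
    VerdictTable,
    roc_curve_points,
)


@dataclass
class StudyBundle:
    """Everything one study contributes to cross-study comparisons."""

    study_id: str
    species: str
    transposon: str
    features: pd.DataFrame
    training: TrainingSet
    verdicts: VerdictTable | None = None
    importances: pd.Series | None = None


def shared_feature_columns(bundles: Sequence[StudyBundle]) -> list[str]:
    """Features present in every bundle, matched by name, in stable order.

    Study-specific features (e.g. the target-sequence feature, absent for a
    motif-free transposon) are dropped before any transfer.
    """
    from .features import FEATURE_COLUMNS

    shared = set(bundles[0].features.columns)
    for b in bundles[1:]:
        shared &= set(b.features.columns)
    cols = [c for c in FEATURE_COLUMNS if c in shared]
    if not cols:
        raise ValueError("no shared feature columns between studies")
    return cols


def transfer_auc(
    train_bundle: StudyBundle,
    test_bundle: StudyBundle,
    train_fraction: float = 0.8,
    seed: int = 0,
    n_trees: int = 200,
) -> float:
    """Train on a stratified 80% of one study's training set; evaluate AUC
    on a stratified 20% of another study's labeled genes.

    With train == test this is a plain within-study holdout. Deterministic
    given the seed.
    """
    cols = shared_feature_columns([train_bundle, test_bundle])

    def _xy(bundle: StudyBundle):
        common = bundle.training.table.index.intersection(bundle.features.index)
        X = bundle.features.loc[common, cols].to_numpy(dtype=float)
        y = bundle.training.binary().loc[common].to_numpy()
        return X, y

    X_tr, y_tr = _xy(train_bundle)
    X_te, y_te = _xy(test_bundle)
    X_fit, _, y_fit, _ = train_test_split(
        X_tr, y_tr, train_size=train_fraction, stratify=y_tr, random_state=seed
    )
    _, X_eval, _, y_eval = train_test_split(
        X_te, y_te, test_size=1.0 - train_fraction, stratify=y_te, random_state=seed
    )
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(X_fit, y_fit)
    scores = clf.predict_proba(X_eval)[:, 1]
    return roc_curve_points(y_eval, scores).auc


def transfer_matrix(
    bundles: Sequence[StudyBundle],
    train_fraction: float = 0.8,
    seed: int = 0,
    n_trees: int = 200,
) -> pd.DataFrame:
    """Train-study x test-study AUC grid; diagonal = within-study holdout."""
    ids = [b.study_id for b in bundles]
    grid = pd.DataFrame(index=pd.Index(ids, name="train"), columns=ids, dtype=float)
    for tr in bundles:
        for te in bundles:
            grid.loc[tr.study_id, te.study_id] = transfer_auc(
                tr, te, train_fraction=train_fraction, seed=seed, n_trees=n_trees
            )
    grid.columns.name = "test"
    return grid


def importance_correlation(bundles: Sequence[StudyBundle]) -> pd.DataFrame:
    """Pearson correlation of relative feature-importance vectors between
    every pair of studies, on the shared feature schema."""
    cols = shared_feature_columns(bundles)
    if len(cols) < 3:
        raise ValueError("need at least 3 shared features for a stable correlation")
    ids = [b.study_id for b in bundles]
    vectors = {}
    for b in bundles:
        if b.importances is None:
            raise ValueError(f"bundle {b.study_id} has no feature importances")
        v = b.importances.reindex(cols)
        vectors[b.study_id] = (v / v.sum()).to_numpy(dtype=float)
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            r = float(np.corrcoef(vectors[a], vectors[ids[j]])[0, 1])
            mat.iloc[i, j] = mat.iloc[j, i] = r
    return mat


def verdict_agreement(
    verdicts_a: VerdictTable,
    verdicts_b: VerdictTable,
    reference_labels: Mapping[str, str],
) -> dict:
    """Three-way agreement between two studies' verdicts and reference
    (literature) essentiality labels.

    Counts every cell of the A x B x reference partition over the common,
    non-excluded ORF universe, and lists the genes both studies call
    essential while the reference lists non-essential — candidate
    false-negatives of deletion collections (or quantitative-fitness genes).
    """
    a = verdicts_a.table[verdicts_a.table["verdict"] != "excluded"]
    b = verdicts_b.table[verdicts_b.table["verdict"] != "excluded"]
    universe = a.index.intersection(b.index).intersection(list(reference_labels))
    if len(universe) == 0:
        raise ValueError("no common ORFs between the two studies and the reference")
    cells: dict[tuple[str, str, str], int] = {}
    both_not_reference: list[str] = []
    for orf in universe:
        va = a.loc[orf, "verdict"]
        vb = b.loc[orf, "verdict"]
        vr = reference_labels[orf]
        cells[(va, vb, vr)] = cells.get((va, vb, vr), 0) + 1
        if va == vb == ESSENTIAL and vr == NON_ESSENTIAL:
            both_not_reference.append(orf)
    return {
        "n_common": int(len(universe)),
        "cells": cells,
        "both_essential_reference_non_essential": sorted(both_not_reference),
    }


def ploidy_compare(
    verdicts_haploid: VerdictTable,
    verdicts_diploid: VerdictTable,
    curation: CurationReport | None = None,
) -> dict:
    """Partition genes by essentiality verdict in haploid vs diploid pools.

    Genes essential in both ploidies are haploinsufficiency candidates —
    after curation, since duplicated/dubious/deleted/short genes dominate
    the raw "essential in both" set. Curation reasons take precedence over
    the verdicts.
    """
    h = verdicts_haploid.table
    d = verdicts_diploid.table
    common = h.index.intersection(d.index)
    buckets: dict[str, list[str]] = {
        "essential_both": [],
        "essential_haploid_only": [],
        "essential_diploid_only": [],
        "non_essential_both": [],
        "excluded": [],
    }
    for orf in common:
        vh, vd = h.loc[orf, "verdict"], d.loc[orf, "verdict"]
        if "excluded" in (vh, vd) or (
            curation is not None and orf in curation.removed_ids
        ):
            buckets["excluded"].append(orf)
        elif vh == ESSENTIAL and vd == ESSENTIAL:
            buckets["essential_both"].append(orf)
        elif vh == ESSENTIAL:
            buckets["essential_haploid_only"].append(orf)
        elif vd == ESSENTIAL:
            buckets["essential_diploid_only"].append(orf)
        else:
            buckets["non_essential_both"].append(orf)
    return {k: sorted(v) for k, v in buckets.items()}
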