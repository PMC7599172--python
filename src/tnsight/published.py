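"""Published summary statistics of six in vivo transposon mutagenesis
screens in yeasts, and recomputation of their derived quantities.

The six studies profile three species (Sc = S. cerevisiae, Sp = S. pombe,
Ca = C. albicans) with three transposons (AcDs: no target motif; Hermes:
TnnnnA; PiggyBac: TTAA). Raw reported rows (insertion/read/target tallies,
classifier AUC) are stored here at their printed precision and units; the
functions below recompute the derived rows (mean reads per insertion,
jackpot ratio, target-saturation percentages) and the depth-vs-performance
correlations from those raw values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STUDY_IDS = ["CaAcDs", "ScAcDs", "ScHermes", "SpHermes", "CaPB", "SpPB"]

# Raw reported per-study values. Units follow the published convention:
# *_1e3 in thousands, *_1e6 in millions. None = not applicable (motif-free
# transposon) or not reported.
PUBLISHED_STUDIES = pd.DataFrame(
    {
        "species": ["Ca", "Sc", "Sc", "Sp", "Ca", "Sp"],
        "transposon": ["AcDs", "AcDs", "Hermes", "Hermes", "PiggyBac", "PiggyBac"],
        "target_motif": [None, None, "TnnnnA", "TnnnnA", "TTAA", "TTAA"],
        "donor": ["genome", "plasmid", "plasmid", "plasmid", "genome", "genome"],
        "n_targets_1e3": [None, None, 1154.84, 1302.41, 120.27, 111.37],
        "unique_insertions_1e3": [588.97, 514.89, 444.41, 382.82, 191.49, 37.50],
        "targets_without_insertion_1e3": [None, None, 924.56, 1110.20, 10.69, 79.09],
        "total_reads_1e6": [84.16, 47.10, 18.22, 23.92, 32.58, 6.14],
        "max_reads_per_insertion_1e3": [3254.83, 2210.55, 11.72, 2355.61, 1301.82, 48.31],
        "sd_reads_per_insertion": [9250, 4357, 137, 5069, 4584, 481],
        "auc": [0.99, 0.99, 0.97, 0.96, 0.94, 0.79],
    },
    index=pd.Index(STUDY_IDS, name="study"),
)


def derived_summary(studies: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute the derived summary rows from the raw reported rows.

    Columns:

    - ``mean_reads_per_insertion``: total reads / unique insertions, full
      precision, and ``mean_reads_per_insertion_printed`` rounded to the
      integer the published table prints.
    - ``max_over_mean_ratio``: highest reads-per-insertion divided by the
      *printed* (integer-rounded) mean — the published convention; the
      full-precision variant is kept alongside.
    - ``pct_targets_without_insertion`` / ``pct_insertions_at_targets``:
      target-saturation percentages on the 0-100 scale.
    """
    df = PUBLISHED_STUDIES if studies is None else studies
    out = pd.DataFrame(index=df.index)
    reads = df["total_reads_1e6"] * 1e6
    ins = df["unique_insertions_1e3"] * 1e3
    mean = reads / ins
    out["mean_reads_per_insertion"] = mean
    out["mean_reads_per_insertion_printed"] = mean.round().astype(int)
    mx = df["max_reads_per_insertion_1e3"] * 1e3
    out["max_over_mean_ratio_full"] = mx / mean
    out["max_over_mean_ratio"] = mx / out["mean_reads_per_insertion_printed"]
    targets = df["n_targets_1e3"] * 1e3
    without = df["targets_without_insertion_1e3"] * 1e3
    out["pct_targets_without_insertion"] = 100.0 * without / targets
    return out


def depth_auc_correlations(
    studies: pd.DataFrame | None = None, exclude: list[str] | None = None
) -> dict[str, float]:
    """Pearson correlation of classifier AUC with library depth.

    Correlates AUC against total unique insertions and against total reads
    across the studies (optionally excluding some, e.g. the sparse SpPB
    library). Returns r and two-sided p for both pairings.
    """
    from .metrics import correlate_depth_vs_auc

    df = PUBLISHED_STUDIES if studies is None else studies
    if exclude:
        df = df.drop(index=exclude)
    return correlate_depth_vs_auc(
        insertions=np.asarray(df["unique_insertions_1e3"], dtype=float),
        reads=np.asarray(df["total_reads_1e6"], dtype=float),
        auc=np.asarray(df["auc"], dtype=float),
    )
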