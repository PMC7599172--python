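"""Library-quality metrics: summary statistics, jackpot diagnostics,
metagene insertion profiles and depth-vs-performance correlations."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .calling import InsertionLibrary
from .genome import ORFRecord, TargetSiteIndex


@dataclass
class LibraryStats:
    unique_insertions: int
    total_reads: int
    mean_reads_per_insertion: float
    sd_reads_per_insertion: float
    max_reads_per_insertion: int
    max_over_mean_ratio: float
    n_sites_reads_gt_1m: int
    mean_insertions_per_gene: float
    n_genes_zero_insertions: int
    # target-dependent fields; None for motif-free transposons
    pct_targets_without_insertion: float | None = None
    pct_insertions_at_targets: float | None = None
    mean_targets_per_gene: float | None = None
    n_genes_zero_targets: int | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def summarize_library(
    lib: InsertionLibrary,
    orfs: Sequence[ORFRecord],
    target_index: TargetSiteIndex | None = None,
    read_threshold: int = 10**6,
) -> LibraryStats:
    """Compute the standard library summary statistics.

    Target-dependent fields are filled only when a target-site index is
    given (motif-bearing transposons). A site counts as "at a target" when
    its coordinate falls anywhere within a motif span [p, p+len); a target
    counts as "hit" when any site falls within its span.
    """
    counts = lib.all_counts()
    if counts.size == 0:
        raise ValueError("cannot summarize an empty insertion library")
    mean = float(counts.mean())
    per_gene = np.array(
        [lib.sites_in(o.chrom, o.start, o.end)[0] for o in orfs], dtype=float
    )
    stats = LibraryStats(
        unique_insertions=lib.unique_insertions,
        total_reads=lib.total_reads,
        mean_reads_per_insertion=mean,
        sd_reads_per_insertion=float(counts.std(ddof=0)),
        max_reads_per_insertion=int(counts.max()),
        max_over_mean_ratio=float(counts.max() / mean),
        n_sites_reads_gt_1m=int((counts > read_threshold).sum()),
        mean_insertions_per_gene=float(per_gene.mean()) if len(per_gene) else 0.0,
        n_genes_zero_insertions=int((per_gene == 0).sum()),
    )
    if target_index is not None:
        mlen = len(target_index.motif)
        n_targets = target_index.total_count
        n_without = 0
        n_sites_at_target = 0
        for chrom, tpos in target_index.positions.items():
            sites = lib.positions.get(chrom, np.array([], dtype=np.int64))
            if len(tpos):
                lo = np.searchsorted(sites, tpos, side="left")
                hi = np.searchsorted(sites, tpos + mlen, side="left")
                n_without += int((hi == lo).sum())
            if len(sites):
                # site is at a target iff the closest target start at or
                # before it is within mlen
                idx = np.searchsorted(tpos, sites, side="right") - 1
                ok = idx >= 0
                ok[ok] &= tpos[idx[ok]] > sites[ok] - mlen
                n_sites_at_target += int(ok.sum())
        per_gene_targets = np.array(
            [
                np.searchsorted(
                    target_index.positions.get(o.chrom, np.array([], dtype=np.int64)),
                    o.end,
                    side="left",
                )
                - np.searchsorted(
                    target_index.positions.get(o.chrom, np.array([], dtype=np.int64)),
                    o.start,
                    side="left",
                )
                for o in orfs
            ],
            dtype=float,
        )
        stats.pct_targets_without_insertion = 100.0 * n_without / n_targets
        stats.pct_insertions_at_targets = (
            100.0 * n_sites_at_target / lib.unique_insertions
        )
        stats.mean_targets_per_gene = (
            float(per_gene_targets.mean()) if len(per_gene_targets) else 0.0
        )
        stats.n_genes_zero_targets = int((per_gene_targets == 0).sum())
    return stats


@dataclass
class JackpotReport:
    sites: list[tuple[str, int, int]]
    n_sites_reads_gt_1m: int
    mean_reads_per_insertion: float


def detect_jackpots(
    lib: InsertionLibrary, fold: float = 1000.0, read_threshold: int = 10**6
) -> JackpotReport:
    """Sites with >= ``fold`` times the library-average reads per insertion.

    Such sites usually descend from a single transposition clone that arose
    before induction and soak up sequencing capacity.
    """
    counts = lib.all_counts()
    if counts.size == 0:
        raise ValueError("cannot scan an empty insertion library")
    mean = float(counts.mean())
    cutoff = fold * mean
    sites = [
        (chrom, pos, count) for chrom, pos, count in lib if count >= cutoff
    ]
    return JackpotReport(
        sites=sites,
        n_sites_reads_gt_1m=int((counts > read_threshold).sum()),
        mean_reads_per_insertion=mean,
    )


def correlate_depth_vs_auc(
    stats_list: Sequence[LibraryStats] | None = None,
    auc_list: Sequence[float] | None = None,
    *,
    insertions: np.ndarray | None = None,
    reads: np.ndarray | None = None,
    auc: np.ndarray | None = None,
) -> dict[str, float]:
    """Pearson r (and two-sided p) of AUC vs unique insertions and vs reads.

    Accepts either a list of :class:`LibraryStats` plus AUCs, or explicit
    arrays. At least 3 paired studies are required.
    """
    if stats_list is not None:
        insertions = np.array([s.unique_insertions for s in stats_list], dtype=float)
        reads = np.array([s.total_reads for s in stats_list], dtype=float)
        auc = np.asarray(auc_list, dtype=float)
    if insertions is None or reads is None or auc is None:
        raise ValueError("need either stats_list+auc_list or explicit arrays")
    if len(auc) < 3:
        raise ValueError("need at least 3 paired studies")
    r_i, p_i = sps.pearsonr(insertions, auc)
    r_r, p_r = sps.pearsonr(reads, auc)
    return {
        "r_insertions": float(r_i),
        "p_insertions": float(p_i),
        "r_reads": float(r_r),
        "p_reads": float(p_r),
    }


@dataclass
class MetageneProfile:
    """Strand-oriented insertion counts around start codons.

    ``offsets`` run from -window to +window; negative = upstream of the
    start codon. ``values`` are insertions per gene per million library
    insertions (summed over the gene subset, divided by subset size and by
    library unique insertions, times 1e6).
    """

    offsets: np.ndarray
    values: np.ndarray
    n_genes: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("offset\tvalue\n")
            for o, v in zip(self.offsets, self.values):
                fh.write(f"{o}\t{v}\n")


def metagene_profile(
    lib: InsertionLibrary,
    orfs: Sequence[ORFRecord],
    window: int = 1000,
    subset: set[str] | None = None,
) -> MetageneProfile:
    """Aggregate insertion sites around start codons for a gene subset.

    Offsets are strand-oriented: for a plus-strand gene, offset = position -
    start; for a minus-strand gene, offset = end - position (so upstream of
    the start codon is negative on both strands). Windows are clipped at
    chromosome ends implicitly (absent positions contribute nothing).
    """
    offsets = np.arange(-window, window + 1)
    values = np.zeros_like(offsets, dtype=float)
    genes = [o for o in orfs if subset is None or o.orf_id in subset]
    for orf in genes:
        if orf.strand == "+":
            lo, hi = orf.start - window, orf.start + window + 1
            for pos in lib.positions_in(orf.chrom, max(lo, 0), hi):
                values[pos - orf.start + window] += 1
        else:
            lo, hi = orf.end - window, orf.end + window + 1
            for pos in lib.positions_in(orf.chrom, max(lo, 0), hi):
                off = orf.end - pos
                if -window <= off <= window:
                    values[off + window] += 1
    if genes and lib.unique_insertions:
        values = values / len(genes) / lib.unique_insertions * 1e6
    return MetageneProfile(offsets=offsets, values=values, n_genes=len(genes))


def upstream_coding_load(
    lib: InsertionLibrary,
    orfs: Sequence[ORFRecord],
    labels: Mapping[str, str],
    span: int = 100,
) -> float:
    """Mean insertions in the first ``span`` coding bp of essential genes,
    normalized per million library insertions.

    Elevated values flag a transposon whose insertion does not reliably
    disrupt the gene (e.g. one carrying cryptic promoter activity), since
    truly disruptive insertions this close to the start codon of an
    essential gene should be lethal. Read counts do not enter: the value
    depends only on site presence.
    """
    ess = [o for o in orfs if labels.get(o.orf_id) == "essential"]
    if not ess:
        raise ValueError("no essential genes in the label set")
    counts = []
    for orf in ess:
        if orf.strand == "+":
            n, _ = lib.sites_in(orf.chrom, orf.start, min(orf.start + span, orf.end))
        else:
            n, _ = lib.sites_in(orf.chrom, max(orf.end - span, orf.start), orf.end)
        counts.append(n)
    return float(np.mean(counts) / lib.unique_insertions * 1e6)
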