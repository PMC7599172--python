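"""Per-ORF predictor features for essentiality classification.

Eight predictors per ORF: raw insertion and read counts, the Neighborhood
Index (local-density-normalized insertion rate), the Freedom Index (largest
insertion-free fraction), upstream insertion count, insertions per target
sequence (motif-bearing transposons only), and length-normalized read and
insertion counts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import InsertionLibrary
from .genome import Genome, ORFRecord

# classifier input columns, in stable order; the target-dependent feature is
# dropped for motif-free transposons
FEATURE_COLUMNS = [
    "insertions",
    "reads",
    "neighborhood_index",
    "freedom_index",
    "insertions_100_upstream",
    "insertions_per_target",
    "reads_per_length",
    "insertions_per_length",
]


def freedom_index(orf: ORFRecord, lib: InsertionLibrary) -> float:
    """Largest insertion-free stretch of the ORF divided by ORF length.

    An insertion-free stretch is a run of bases within [start, end) that
    contains no insertion site: the flank before the first site and after
    the last site both count. FI = 1 iff the ORF has no insertions; values
    near 1 in a data-rich region suggest an intolerant (essential) gene or
    domain.
    """
    pos = lib.positions_in(orf.chrom, orf.start, orf.end)
    if len(pos) == 0:
        return 1.0
    gaps = np.diff(pos) - 1
    leading = pos[0] - orf.start
    trailing = orf.end - 1 - pos[-1]
    longest = max(int(leading), int(trailing), int(gaps.max()) if len(gaps) else 0)
    return longest / orf.length


def neighborhood_index(
    orf: ORFRecord,
    lib: InsertionLibrary,
    chrom_length: int,
    flank: int = 10_000,
) -> tuple[float, int]:
    """ORF insertion density relative to its local neighborhood.

    NI = (n_orf / L_orf) / (n_window / L_window) with the window extending
    ``flank`` bp to each side of the ORF, clipped at chromosome ends, and
    n_window including the ORF's own insertions. Normalizes away positional
    biases (donor-locus proximity, chromatin accessibility). Returns
    (NI, n_window); an empty window gives NI = 0 and is flagged upstream.
    """
    n_orf, _ = lib.sites_in(orf.chrom, orf.start, orf.end)
    wstart = max(orf.start - flank, 0)
    wend = min(orf.end + flank, chrom_length)
    n_window, _ = lib.sites_in(orf.chrom, wstart, wend)
    if n_window == 0:
        return 0.0, 0
    orf_density = n_orf / orf.length
    window_density = n_window / (wend - wstart)
    return orf_density / window_density, n_window


def upstream_insertions(
    orf: ORFRecord,
    lib: InsertionLibrary,
    chrom_length: int,
    span: int = 100,
) -> int:
    """Insertions in the ``span`` bp 5' of the start codon (strand-oriented).

    The start-codon base itself belongs to the ORF, not the upstream window.
    """
    if orf.strand == "+":
        lo, hi = max(orf.start - span, 0), orf.start
    else:
        lo, hi = orf.end, min(orf.end + span, chrom_length)
    n, _ = lib.sites_in(orf.chrom, lo, hi)
    return n


def compute_features(
    lib: InsertionLibrary,
    orfs: Sequence[ORFRecord],
    target_counts: Mapping[str, int] | None = None,
    genome: Genome | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    flank: int = 10_000,
    upstream_span: int = 100,
) -> pd.DataFrame:
    """Assemble the full per-ORF feature table.

    ``target_counts`` enables the insertions-per-target feature (omit for a
    motif-free transposon). Chromosome lengths (for window clipping) come
    from ``genome`` or ``chrom_lengths``. Zero-denominator cases yield 0
    with an explicit flag column (``no_target``, ``no_local_data``) so the
    classifier always sees finite values.
    """
    if genome is not None:
        lengths = {c: genome.length(c) for c in genome}
    elif chrom_lengths is not None:
        lengths = dict(chrom_lengths)
    else:
        raise ValueError("need genome or chrom_lengths for window clipping")

    rows = []
    for orf in orfs:
        if orf.chrom not in lengths:
            raise ValueError(f"ORF {orf.orf_id} on unknown chromosome {orf.chrom!r}")
        clen = lengths[orf.chrom]
        n_ins, n_reads = lib.sites_in(orf.chrom, orf.start, orf.end)
        ni, n_window = neighborhood_index(orf, lib, clen, flank=flank)
        row = {
            "orf_id": orf.orf_id,
            "orf_length": orf.length,
            "insertions": n_ins,
            "reads": n_reads,
            "neighborhood_index": ni,
            "freedom_index": freedom_index(orf, lib),
            "insertions_100_upstream": upstream_insertions(
                orf, lib, clen, span=upstream_span
            ),
            "reads_per_length": n_reads / orf.length,
            "insertions_per_length": n_ins / orf.length,
            "n_window": n_window,
            "no_local_data": n_window == 0,
        }
        if target_counts is not None:
            nt = int(target_counts.get(orf.orf_id, 0))
            row["n_targets"] = nt
            row["insertions_per_target"] = n_ins / nt if nt > 0 else 0.0
            row["no_target"] = nt == 0
        rows.append(row)
    df = pd.DataFrame(rows).set_index("orf_id")
    return df


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The classifier input columns present in a feature table, in order."""
    return [c for c in FEATURE_COLUMNS if c in table.columns]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the table as TSV plus a sidecar JSON column schema."""
    table.to_csv(path, sep="\t")
    schema = {
        "index": "orf_id",
        "columns": {c: str(table[c].dtype) for c in table.columns},
        "classifier_features": feature_columns(table),
    }
    with open(str(path) + ".schema.json", "w") as fh:
        json.dump(schema, fh, indent=2)
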