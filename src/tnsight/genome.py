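"""Genomes, ORF annotations and transposon target-site scanning.

Coordinate convention: every interval in this package is 0-based, half-open
``[start, end)``. GFF3 input (1-based, inclusive) is converted once, at the
I/O boundary, and converted back only when writing GFF-like output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

_VALID_BASES = set("ACGTN")

# Degenerate nucleotide codes; only N is used by the built-in motifs but the
# scanner accepts the full IUPAC set.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class Genome:
    """A set of chromosome sequences, uppercased, alphabet {A,C,G,T,N}.

    ``masked_fraction`` records, per chromosome, the fraction of bases that
    were soft-masked (lowercase) in the source FASTA; the sequence itself is
    stored uppercase.
    """

    sequences: dict[str, str]
    masked_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {chrom!r} has an empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {chrom!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self):
        return iter(self.sequences)


@dataclass(frozen=True)
class ORFRecord:
    """A gene/ORF interval; ``start``/``end`` are 0-based half-open."""

    orf_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.orf_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.orf_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TargetMotif:
    """A transposase target sequence, possibly degenerate (N = any base)."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError("motif pattern must be at least 2 bp")
        bad = set(self.pattern.upper()) - set(_IUPAC)
        if bad:
            raise ValueError(f"motif contains unknown codes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, seq: str, pos: int = 0) -> bool:
        """Exact degenerate match of the motif at ``seq[pos:pos+len]``.

        N (or any ambiguity code) in the *genome* never matches a fixed base,
        so gapped assembly stretches do not inflate target counts.
        """
        window = seq[pos : pos + len(self.pattern)]
        if len(window) < len(self.pattern):
            return False
        for base, code in zip(window, self.pattern.upper()):
            if base not in _IUPAC.get(code, ""):
                return False
        return True

    def regex(self) -> re.Pattern:
        body = "".join(
            b if b in "ACGT" else "[" + _IUPAC[b] + "]" for b in self.pattern.upper()
        )
        # lookahead so overlapping occurrences are all reported
        return re.compile(rf"(?=({body}))")


# The two built-in target sequences. Both pattern families are their own
# reverse complements (TTAA exactly; TNNNNA as a family), so a forward-strand
# scan enumerates every genomic target.
TTAA = TargetMotif("TTAA", "TTAA")
TNNNNA = TargetMotif("TnnnnA", "TNNNNA")

MOTIFS: dict[str, TargetMotif | None] = {
    "TTAA": TTAA,
    "TnnnnA": TNNNNA,
    "none": None,
}


@dataclass
class TargetSiteIndex:
    """Sorted per-chromosome start positions of motif matches."""

    motif: TargetMotif
    positions: dict[str, np.ndarray]

    @property
    def total_count(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.positions):
                for p in self.positions[chrom]:
                    fh.write(f"{chrom}\t{p}\t{p + len(self.motif)}\t{self.motif.name}\n")


def read_fasta(path: str | Path) -> Genome:
    """Read a (multi-)FASTA into a :class:`Genome`.

    Lowercase (soft-masked) bases are uppercased; the masked fraction is
    retained per chromosome. Duplicate record ids raise.
    """
    sequences: dict[str, str] = {}
    masked: dict[str, float] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        raw = str(rec.seq)
        if not raw:
            raise ValueError(f"FASTA record {rec.id!r} is empty")
        n_lower = sum(1 for c in raw if c.islower())
        sequences[rec.id] = raw.upper()
        masked[rec.id] = n_lower / len(raw)
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(sequences, masked)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff(
    path: str | Path,
    feature_types: Sequence[str] = ("gene", "CDS"),
    id_attribute: str = "ID",
    genome: Genome | None = None,
) -> list[ORFRecord]:
    """Read ORF records from a GFF3 file.

    1-based inclusive coordinates become 0-based half-open. Records are
    sorted by (chrom, start). Features whose chromosome is absent from
    ``genome`` (when given) are dropped with a count attached to the returned
    list as ``.n_unknown_chrom``; malformed intervals (start > end) are
    rejected the same way via ``.n_rejected``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    records: list[ORFRecord] = []
    seen: set[str] = set()
    n_rejected = 0
    n_unknown = 0
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            attrs = dict(feat.attributes)
            orf_id = attrs.get(id_attribute, [feat.id])[0]
            if feat.start > feat.end:
                n_rejected += 1
                continue
            if genome is not None and feat.seqid not in genome:
                n_unknown += 1
                continue
            if orf_id in seen:
                raise ValueError(f"duplicate feature id {orf_id!r} in {path}")
            seen.add(orf_id)
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            records.append(
                ORFRecord(orf_id, feat.seqid, feat.start - 1, feat.end, strand)
            )
    records.sort(key=lambda r: (r.chrom, r.start))
    out = _ORFList(records)
    out.n_rejected = n_rejected
    out.n_unknown_chrom = n_unknown
    return out


class _ORFList(list):
    """A list of ORFRecord with I/O bookkeeping attributes."""

    n_rejected: int = 0
    n_unknown_chrom: int = 0


def write_gff(orfs: Iterable[ORFRecord], path: str | Path, feature_type: str = "gene") -> None:
    """Write ORFs as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in orfs:
            fh.write(
                f"{orf.chrom}\ttnsight\t{feature_type}\t{orf.start + 1}\t{orf.end}\t.\t"
                f"{orf.strand}\t.\tID={orf.orf_id}\n"
            )


def scan_target_sites(genome: Genome, motif: TargetMotif) -> TargetSiteIndex:
    """Find every (possibly overlapping) forward-strand motif match.

    Both built-in motifs are reverse-complement-palindromic pattern families,
    so this single-strand scan is complete.
    """
    rx = motif.regex()
    positions = {
        chrom: np.array([m.start() for m in rx.finditer(seq)], dtype=np.int64)
        for chrom, seq in genome.sequences.items()
    }
    return TargetSiteIndex(motif, positions)


def count_targets_per_orf(
    index: TargetSiteIndex, orfs: Sequence[ORFRecord]
) -> dict[str, int]:
    """Targets per ORF: a match counts iff its START lies in [start, end).

    Overlapping ORFs each count a shared target independently.
    """
    counts: dict[str, int] = {}
    for orf in orfs:
        pos = index.positions.get(orf.chrom)
        if pos is None or len(pos) == 0:
            counts[orf.orf_id] = 0
            continue
        lo = np.searchsorted(pos, orf.start, side="left")
        hi = np.searchsorted(pos, orf.end, side="left")
        counts[orf.orf_id] = int(hi - lo)
    return counts


def targets_per_orf_table(
    index: TargetSiteIndex, orfs: Sequence[ORFRecord]
) -> pd.DataFrame:
    """Per-ORF target counts with per-kb density, as a tidy table."""
    counts = count_targets_per_orf(index, orfs)
    rows = [
        {
            "orf_id": orf.orf_id,
            "n_targets": counts[orf.orf_id],
            "targets_per_kb": 1000.0 * counts[orf.orf_id] / orf.length,
        }
        for orf in orfs
    ]
    return pd.DataFrame(rows)


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
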