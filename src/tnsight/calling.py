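"""From transposon-tagged reads to a deduplicated insertion map.

The central object is :class:`InsertionLibrary`: the set of unique genomic
coordinates at which a transposon-genome junction was observed, each with the
number of supporting reads. Site identity deliberately ignores read strand —
both orientations collapse onto one forward-strand coordinate, so a site hit
from both transposon ends is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .genome import Genome, reverse_complement


@dataclass(frozen=True)
class TrimSpec:
    """How to locate and remove the transposon tag from a raw read.

    ``post_tag_offset`` skips extra bases between the tag match and the first
    genomic base (some chemistries leave a fixed-length stub, e.g. 3 bp).
    A single mismatch is tolerated in the tag when it is >= 20 bp long.
    """

    tag_sequence: str
    min_overlap: int = 10
    post_tag_offset: int = 0
    min_remaining_length: int = 2
    discard_untrimmed: bool = True

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.post_tag_offset < 0:
            raise ValueError("post_tag_offset must be >= 0")


def _find_with_mismatch(read: str, tag: str, max_mm: int) -> int:
    """Leftmost start of ``tag`` in ``read`` allowing ``max_mm`` mismatches."""
    if max_mm == 0:
        return read.find(tag)
    n, m = len(read), len(tag)
    for i in range(n - m + 1):
        mm = 0
        for a, b in zip(read[i : i + m], tag):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return i
    return -1


def trim_transposon_tag(read_sequence: str, spec: TrimSpec) -> str | None:
    """Return the genomic portion of a tagged read, or ``None`` if rejected.

    The tag is searched as a full match anywhere in the read (1 mismatch
    allowed for tags >= 20 bp), or as a partial match: a suffix of the tag of
    length >= ``min_overlap`` at the read start (the end adjoining the
    genomic sequence).
    """
    read = read_sequence.upper()
    tag = spec.tag_sequence.upper()
    max_mm = 1 if len(tag) >= 20 else 0

    tag_end = -1
    hit = _find_with_mismatch(read, tag, max_mm)
    if hit >= 0:
        tag_end = hit + len(tag)
    else:
        # read may begin mid-tag: longest tag suffix that prefixes the read
        for l in range(len(tag) - 1, spec.min_overlap - 1, -1):
            if read.startswith(tag[-l:]):
                tag_end = l
                break

    if tag_end < 0:
        return None if spec.discard_untrimmed else read
    out = read[tag_end + spec.post_tag_offset :]
    if len(out) < spec.min_remaining_length:
        return None
    return out


@dataclass
class TrimReport:
    n_input: int = 0
    n_trimmed: int = 0
    n_rejected: int = 0


def trim_reads(
    reads: Iterable[str], spec: TrimSpec
) -> tuple[list[str], TrimReport]:
    """Trim a batch of read sequences; rejected reads are counted, not kept."""
    report = TrimReport()
    out: list[str] = []
    for read in reads:
        report.n_input += 1
        trimmed = trim_transposon_tag(read, spec)
        if trimmed is None:
            report.n_rejected += 1
        else:
            report.n_trimmed += 1
            out.append(trimmed)
    return out, report


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read reduced to what insertion calling needs.

    ``pos`` is the 0-based leftmost aligned base; ``length`` the aligned
    span on the reference. ``first_base_matches_reference`` reports whether
    the first *sequenced* base (the junction base; the rightmost aligned base
    for minus-strand reads) matches the reference.
    """

    chrom: str
    pos: int
    strand: str
    mapq: int
    length: int = 1
    first_base_matches_reference: bool = True


@dataclass
class InsertionLibrary:
    """Unique insertion sites with read counts, sorted by (chrom, position)."""

    positions: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, int, int]],
        metadata: dict | None = None,
    ) -> "InsertionLibrary":
        """Build from (chrom, position, read_count) records, collapsing
        duplicate coordinates by summing counts."""
        acc: dict[str, dict[int, int]] = {}
        for chrom, pos, count in records:
            acc.setdefault(chrom, {})
            acc[chrom][pos] = acc[chrom].get(pos, 0) + int(count)
        positions = {}
        counts = {}
        for chrom, d in acc.items():
            ps = np.array(sorted(d), dtype=np.int64)
            positions[chrom] = ps
            counts[chrom] = np.array([d[p] for p in ps], dtype=np.int64)
        return cls(positions, counts, metadata or {})

    @property
    def unique_insertions(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    @property
    def total_reads(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self.positions):
            for p, c in zip(self.positions[chrom], self.counts[chrom]):
                yield chrom, int(p), int(c)

    def all_counts(self) -> np.ndarray:
        if not self.counts:
            return np.array([], dtype=np.int64)
        return np.concatenate([self.counts[c] for c in sorted(self.counts)])

    def sites_in(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """(n_sites, n_reads) with coordinate in [start, end)."""
        pos = self.positions.get(chrom)
        if pos is None or len(pos) == 0:
            return 0, 0
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="left"))
        return hi - lo, int(self.counts[chrom][lo:hi].sum())

    def positions_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        pos = self.positions.get(chrom)
        if pos is None or len(pos) == 0:
            return np.array([], dtype=np.int64)
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return pos[lo:hi]

    # ---- I/O -------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: chrom, 0-based position, read_count."""
        with open(path, "w") as fh:
            fh.write("chrom\tposition\tread_count\n")
            for chrom, pos, count in self:
                fh.write(f"{chrom}\t{pos}\t{count}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, metadata: dict | None = None) -> "InsertionLibrary":
        df = pd.read_csv(path, sep="\t")
        return cls.from_records(
            zip(df["chrom"], df["position"], df["read_count"]), metadata
        )

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write('track type=bedGraph name="insertions"\n')
            for chrom, pos, count in self:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{count}\n")


def call_insertions(
    aligned_reads: Iterable[AlignedRead],
    mapq_min: int = 20,
    require_first_base_match: bool = True,
    genome: Genome | None = None,
    metadata: dict | None = None,
) -> InsertionLibrary:
    """Collapse filtered aligned reads into an insertion map.

    Reads with MAPQ below ``mapq_min`` or with a mismatch at the junction
    base are dropped. The junction coordinate is the leftmost aligned base
    for plus-strand reads and the rightmost for minus-strand reads; both
    orientations collapse onto one forward-strand coordinate.
    """
    records: list[tuple[str, int, int]] = []
    for read in aligned_reads:
        if genome is not None and read.chrom not in genome:
            raise ValueError(f"read maps to unknown chromosome {read.chrom!r}")
        if read.mapq < mapq_min:
            continue
        if require_first_base_match and not read.first_base_matches_reference:
            continue
        junction = read.pos if read.strand == "+" else read.pos + read.length - 1
        records.append((read.chrom, junction, 1))
    return InsertionLibrary.from_records(records, metadata)


def merge_libraries(libs: Sequence[InsertionLibrary]) -> InsertionLibrary:
    """Union of sites, read counts summed at identical coordinates."""
    if not libs:
        raise ValueError("no libraries to merge")
    species = {l.metadata.get("species") for l in libs} - {None}
    if len(species) > 1:
        raise ValueError(f"conflicting species metadata: {sorted(species)}")
    records = [rec for lib in libs for rec in lib]
    meta = dict(libs[0].metadata)
    meta["merged_from"] = [l.metadata.get("study", f"lib{i}") for i, l in enumerate(libs)]
    return InsertionLibrary.from_records(records, meta)


def naive_exact_mapper(genome: Genome, sequences: Iterable[str]) -> list[AlignedRead]:
    """Place reads by exact full-length match (fixture-scale stand-in for a
    real aligner).

    Uniquely matching reads (forward or reverse-complement) get MAPQ 42;
    multi-mapping reads get MAPQ 0, so the downstream MAPQ filter removes
    them — duplicated regions therefore end up with few if any called sites.
    Non-matching reads are dropped.
    """
    out: list[AlignedRead] = []
    for seq in sequences:
        seq = seq.upper()
        rc = reverse_complement(seq)
        hits: list[tuple[str, int, str]] = []
        for chrom, ref in genome.sequences.items():
            for query, strand in ((seq, "+"), (rc, "-")):
                start = ref.find(query)
                while start >= 0 and len(hits) < 2:
                    hits.append((chrom, start, strand))
                    start = ref.find(query, start + 1)
            if len(hits) >= 2:
                break
        if not hits:
            continue
        chrom, pos, strand = hits[0]
        mapq = 42 if len(hits) == 1 else 0
        out.append(
            AlignedRead(chrom, pos, strand, mapq, length=len(seq),
                        first_base_matches_reference=True)
        )
    return out


def read_fastq_sequences(path: str | Path) -> list[str]:
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def read_sam(path: str | Path, genome: Genome | None = None) -> list[AlignedRead]:
    """Load aligned reads from SAM/BAM via pysam.

    The junction-base check compares the first sequenced base against the
    reference when a genome is supplied; otherwise it falls back to a custom
    ``fm:i`` tag (1/0) if present, else assumes a match.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            strand = "-" if rec.is_reverse else "+"
            length = rec.reference_length or len(rec.query_sequence)
            first_ok = True
            if genome is not None and rec.reference_name in genome:
                ref = genome.sequences[rec.reference_name]
                qseq = rec.query_alignment_sequence
                if strand == "+":
                    first_ok = ref[rec.reference_start] == qseq[0].upper()
                else:
                    first_ok = ref[rec.reference_start + length - 1] == qseq[-1].upper()
            elif rec.has_tag("fm"):
                first_ok = bool(rec.get_tag("fm"))
            out.append(
                AlignedRead(
                    rec.reference_name,
                    rec.reference_start,
                    strand,
                    rec.mapping_quality,
                    length=length,
                    first_base_matches_reference=first_ok,
                )
            )
    return out
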