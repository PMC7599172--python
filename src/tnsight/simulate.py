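"""Synthetic genomes, annotations and transposon insertion libraries.

The generator reproduces the statistical structure the inference pipeline
relies on: motif-constrained per-site insertion intensity (TTAA strict /
TnnnnA preferred / motif-free), distance-decay reinsertion bias around a
chromosomal donor locus, near-zero insertion rates inside essential ORFs
with a tolerated 5' fringe, heavily overdispersed read counts per site, and
rare jackpot sites carrying orders of magnitude more reads than average.
Identical (config, seed) always yields identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .calling import InsertionLibrary, TrimSpec
from .genome import (
    Genome,
    MOTIFS,
    ORFRecord,
    TargetMotif,
    reverse_complement,
    scan_target_sites,
    write_fasta,
    write_gff,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for a simulated mutagenesis screen.

    Defaults describe an AcDs-like screen of a compact yeast-like genome:
    1 Mb over two chromosomes at 40% GC, 500 non-overlapping ORFs
    (300-3000 bp, mean ~1 kb), 20% essential, 100k unique insertions with
    essential ORFs suppressed to 2% of the baseline intensity beyond a 35 bp
    tolerated 5' fringe, gamma-Poisson read counts (mean 100, dispersion
    0.5, so sd >> mean as real libraries show), and on average one jackpot
    clone per library.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    gc_content: float = 0.40
    n_orfs: int = 500
    orf_length_min: int = 300
    orf_length_max: int = 2000
    orf_length_mean: int = 1000
    essential_fraction: float = 0.20
    transposon: str = "acds_like"  # acds_like | hermes_like | pb_like
    motif_weight: float = 10.0  # on-motif preference for hermes_like
    off_motif_rate: float = 0.0  # pb_like leak off the strict motif
    donor: str = "plasmid"  # plasmid | chromosomal
    donor_chrom: str = "chrI"
    donor_pos: int = 250_000
    donor_decay_bp: float = 50_000.0  # lambda of the exponential decay
    donor_bias: float = 10.0  # b: peak fold-excess at the donor
    n_insertions: int = 100_000
    essential_suppression: float = 0.02  # epsilon
    fringe_bp: int = 35
    read_mean: float = 100.0  # mu of the gamma-Poisson read-count model
    read_dispersion: float = 0.5  # k; smaller = heavier overdispersion
    jackpot_rate: float = 1.0  # expected jackpot clones per library
    jackpot_multiplier_range: tuple[float, float] = (1e3, 1e5)  # x read_mean

    def __post_init__(self) -> None:
        for name in ("gc_content", "essential_fraction", "essential_suppression",
                     "off_motif_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.donor_decay_bp <= 0:
            raise ValueError("donor_decay_bp must be positive")
        if self.transposon not in ("acds_like", "hermes_like", "pb_like"):
            raise ValueError(f"unknown transposon model {self.transposon!r}")
        if self.motif_weight < 1:
            raise ValueError("motif_weight must be >= 1")

    @property
    def motif(self) -> TargetMotif | None:
        return {
            "acds_like": None,
            "hermes_like": MOTIFS["TnnnnA"],
            "pb_like": MOTIFS["TTAA"],
        }[self.transposon]


@dataclass
class SimTruth:
    """Ground truth of a simulation run, for recovery tests."""

    labels: dict[str, str]
    site_intensity: dict[str, np.ndarray] = field(default_factory=dict)
    jackpot_sites: list[tuple[str, int, int]] = field(default_factory=list)


def _chrom_name(i: int) -> str:
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
             "XI", "XII", "XIII", "XIV", "XV", "XVI"]
    return f"chr{roman[i]}" if i < len(roman) else f"chr{i + 1}"


def simulate_genome(config: SimConfig) -> tuple[Genome, list[ORFRecord], SimTruth]:
    """Draw an i.i.d. genome, place non-overlapping ORFs, assign labels."""
    rng = np.random.default_rng([config.seed, 1])
    g = config.gc_content
    probs = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]  # A C G T
    sequences = {}
    for i in range(config.n_chromosomes):
        idx = rng.choice(4, size=config.chrom_length, p=probs)
        sequences[_chrom_name(i)] = _BASES[idx].tobytes().decode()
    genome = Genome(sequences)

    chroms = list(sequences)
    # triangular lengths; the mode is chosen so the distribution mean equals
    # the configured mean (mean of triangular = (min + mode + max) / 3)
    mode = 3 * config.orf_length_mean - config.orf_length_min - config.orf_length_max
    mode = min(max(mode, config.orf_length_min), config.orf_length_max)
    lengths = rng.triangular(
        config.orf_length_min, mode, config.orf_length_max,
        size=config.n_orfs,
    ).astype(int)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    orfs: list[ORFRecord] = []
    import bisect

    # longest-first placement packs dense configurations far more reliably
    # and stays deterministic
    order = np.argsort(-lengths, kind="stable")
    for j, L in ((int(j), int(lengths[j])) for j in order):
        placed = False
        for _ in range(500):
            chrom = chroms[rng.integers(len(chroms))]
            clen = config.chrom_length
            if L >= clen:
                continue
            start = int(rng.integers(0, clen - L))
            ivs = occupied[chrom]
            k = bisect.bisect_left(ivs, (start, start + int(L)))
            # require a gap to both neighbors
            if k > 0 and ivs[k - 1][1] > start:
                continue
            if k < len(ivs) and ivs[k][0] < start + int(L):
                continue
            ivs.insert(k, (start, start + int(L)))
            strand = "+" if rng.random() < 0.5 else "-"
            orfs.append(ORFRecord(f"ORF{j + 1:04d}", chrom, start, start + int(L), strand))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "could not place all ORFs without overlap; reduce n_orfs or "
                "orf lengths, or enlarge the genome"
            )
    orfs.sort(key=lambda o: (o.chrom, o.start))
    labels = {
        o.orf_id: ("essential" if rng.random() < config.essential_fraction
                   else "non_essential")
        for o in orfs
    }
    return genome, orfs, SimTruth(labels=labels)


def _intensity_arrays(
    genome: Genome,
    orfs: Sequence[ORFRecord],
    labels: Mapping[str, str],
    config: SimConfig,
) -> dict[str, np.ndarray]:
    """Per-base insertion intensity implementing all four biases."""
    motif = config.motif
    weights: dict[str, np.ndarray] = {}
    for chrom, seq in genome.sequences.items():
        L = len(seq)
        w = np.ones(L)
        if motif is not None:
            covered = np.zeros(L, dtype=bool)
            index = scan_target_sites(
                Genome({chrom: seq}), motif
            ).positions[chrom]
            for off in range(len(motif)):
                covered[np.minimum(index + off, L - 1)] = True
            if config.transposon == "pb_like":
                w = np.where(covered, 1.0, config.off_motif_rate)
            else:
                w = np.where(covered, config.motif_weight, 1.0)
        if config.donor == "chromosomal" and chrom == config.donor_chrom:
            dist = np.abs(np.arange(L) - config.donor_pos)
            w = w * (1.0 + config.donor_bias * np.exp(-dist / config.donor_decay_bp))
        weights[chrom] = w
    for orf in orfs:
        if labels.get(orf.orf_id) != "essential":
            continue
        if orf.strand == "+":
            lo, hi = orf.start + config.fringe_bp, orf.end
        else:
            lo, hi = orf.start, orf.end - config.fringe_bp
        if lo < hi:
            weights[orf.chrom][lo:hi] *= config.essential_suppression
    return weights


def simulate_library(
    genome: Genome,
    orfs: Sequence[ORFRecord],
    labels: Mapping[str, str],
    config: SimConfig,
) -> tuple[InsertionLibrary, SimTruth]:
    """Sample unique insertion sites and overdispersed read counts.

    Sites are a weighted sample without replacement (Gumbel top-k) from the
    per-base intensity; read counts are gamma-Poisson (truncated at 1, since
    a site with zero reads is unobservable); jackpots multiply a random
    site's count up to the configured range.
    """
    rng = np.random.default_rng([config.seed, 2])
    weights = _intensity_arrays(genome, orfs, labels, config)
    chroms = sorted(weights)
    concat = np.concatenate([weights[c] for c in chroms])
    capacity = int((concat > 0).sum())
    if config.n_insertions > capacity:
        raise ValueError(
            f"requested {config.n_insertions} unique insertions but only "
            f"{capacity} positions have nonzero intensity "
            f"(motif capacity limit for {config.transposon})"
        )
    with np.errstate(divide="ignore"):
        logw = np.log(concat)
    gumbel = rng.gumbel(size=concat.size)
    keys = logw + gumbel
    flat_idx = np.argpartition(-keys, config.n_insertions)[: config.n_insertions]
    flat_idx.sort()

    counts = rng.poisson(
        rng.gamma(
            config.read_dispersion,
            config.read_mean / config.read_dispersion,
            size=config.n_insertions,
        )
    )
    counts = np.maximum(counts, 1)

    n_jack = int(rng.poisson(config.jackpot_rate))
    jackpot_positions = (
        rng.choice(config.n_insertions, size=n_jack, replace=False)
        if n_jack
        else np.array([], dtype=int)
    )
    lo, hi = config.jackpot_multiplier_range
    for j in jackpot_positions:
        mult = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
        counts[j] = int(mult * config.read_mean)

    bounds = np.cumsum([0] + [len(weights[c]) for c in chroms])
    records = []
    truth = SimTruth(labels=dict(labels))
    jackset = set(jackpot_positions.tolist())
    site_int: dict[str, list[float]] = {c: [] for c in chroms}
    for k, fi in enumerate(flat_idx):
        ci = int(np.searchsorted(bounds, fi, side="right") - 1)
        chrom = chroms[ci]
        pos = int(fi - bounds[ci])
        records.append((chrom, pos, int(counts[k])))
        site_int[chrom].append(float(weights[chrom][pos]))
        if k in jackset:
            truth.jackpot_sites.append((chrom, pos, int(counts[k])))
    truth.site_intensity = {c: np.array(v) for c, v in site_int.items()}
    meta = {
        "species": "synthetic",
        "transposon": config.transposon,
        "donor": config.donor,
        "seed": config.seed,
    }
    return InsertionLibrary.from_records(records, meta), truth


def emit_reads(
    lib: InsertionLibrary,
    genome: Genome,
    trimspec: TrimSpec,
    read_length: int = 60,
    seed: int = 0,
    max_reads_per_site: int | None = None,
) -> list[tuple[str, str]]:
    """Turn an insertion map back into tagged reads (id, sequence).

    Each read is tag + offset filler + genomic sequence whose first genomic
    base is the insertion coordinate; orientation is random per read (when
    both fit on the chromosome), so the round trip through trimming, mapping
    and insertion calling must collapse the two orientations correctly.
    """
    rng = np.random.default_rng([seed, 3])
    tag = trimspec.tag_sequence.upper()
    glen = read_length - len(tag) - trimspec.post_tag_offset
    if glen < 10:
        raise ValueError("read_length leaves too little genomic sequence")
    reads: list[tuple[str, str]] = []
    for chrom, pos, count in lib:
        seq = genome.sequences[chrom]
        n = count if max_reads_per_site is None else min(count, max_reads_per_site)
        for r in range(n):
            plus_ok = pos + glen <= len(seq)
            minus_ok = pos - glen + 1 >= 0
            if plus_ok and minus_ok:
                strand = "+" if rng.random() < 0.5 else "-"
            elif plus_ok:
                strand = "+"
            elif minus_ok:
                strand = "-"
            else:
                raise ValueError(f"chromosome {chrom} too short for read_length")
            if strand == "+":
                genomic = seq[pos : pos + glen]
            else:
                genomic = reverse_complement(seq[pos - glen + 1 : pos + 1])
            filler = "".join(
                "ACGT"[i] for i in rng.integers(0, 4, size=trimspec.post_tag_offset)
            )
            reads.append((f"{chrom}:{pos}:{r}:{strand}", tag + filler + genomic))
    return reads


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(
    outdir: str | Path, config: SimConfig, emit_fastq: bool = False,
    trimspec: TrimSpec | None = None,
) -> dict:
    """Write a complete simulated study to disk with a manifest.

    Produces genome.fasta, orfs.gff3, labels.csv, insertions.tsv (and
    optionally reads.fastq), plus manifest.json echoing the config, seed and
    file digests so every artifact is reproducible.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, orfs, truth = simulate_genome(config)
    lib, truth = simulate_library(genome, orfs, truth.labels, config)
    write_fasta(genome, outdir / "genome.fasta")
    write_gff(orfs, outdir / "orfs.gff3")
    with open(outdir / "labels.csv", "w") as fh:
        fh.write("orf_id,label\n")
        for orf_id, label in truth.labels.items():
            fh.write(f"{orf_id},{label}\n")
    lib.to_tsv(outdir / "insertions.tsv")
    files = ["genome.fasta", "orfs.gff3", "labels.csv", "insertions.tsv"]
    if emit_fastq:
        spec = trimspec or TrimSpec(tag_sequence="TTGGTTACGCAG", min_overlap=6)
        reads = emit_reads(lib, genome, spec, seed=config.seed,
                           max_reads_per_site=3)
        write_fastq(reads, outdir / "reads.fastq")
        files.append("reads.fastq")
    cfg = asdict(config)
    cfg["jackpot_multiplier_range"] = list(config.jackpot_multiplier_range)
    manifest = {
        "config": cfg,
        "seed": config.seed,
        "files": {f: _sha256(outdir / f) for f in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
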