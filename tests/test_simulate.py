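"""The synthetic-data generator: statistical structure and determinism."""

import json

import numpy as np
import pytest

from tnsight.calling import TrimSpec, call_insertions, naive_exact_mapper, trim_reads
from tnsight.genome import MOTIFS, scan_target_sites
from tnsight.simulate import (
    SimConfig,
    emit_reads,
    simulate_genome,
    simulate_library,
    write_fixture,
)


def small_config(**kw):
    base = dict(seed=0, n_chromosomes=1, chrom_length=100_000, n_orfs=50,
                n_insertions=6_000, jackpot_rate=0.0)
    base.update(kw)
    return SimConfig(**base)


class TestSimulateGenome:
    def test_gc_content_within_binomial_ci(self):
        cfg = SimConfig(seed=0, n_chromosomes=1, chrom_length=1_000_000,
                        n_orfs=10, gc_content=0.5)
        genome, _, _ = simulate_genome(cfg)
        seq = genome.sequences["chrI"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.005

    def test_essential_fraction_within_binomial_noise(self):
        cfg = SimConfig(seed=1, essential_fraction=0.2, n_orfs=500)
        _, _, truth = simulate_genome(cfg)
        n_ess = sum(1 for v in truth.labels.values() if v == "essential")
        # 100 +/- 4 sd of Binomial(500, 0.2)
        assert abs(n_ess - 100) < 4 * np.sqrt(500 * 0.2 * 0.8)

    def test_orfs_non_overlapping(self):
        _, orfs, _ = simulate_genome(small_config())
        by_chrom = {}
        for o in orfs:
            by_chrom.setdefault(o.chrom, []).append((o.start, o.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_deterministic_given_seed(self, tmp_path):
        cfg = small_config(seed=9)
        g1, o1, t1 = simulate_genome(cfg)
        g2, o2, t2 = simulate_genome(cfg)
        assert g1.sequences == g2.sequences
        assert o1 == o2 and t1.labels == t2.labels

    def test_impossible_placement_raises(self):
        with pytest.raises(RuntimeError, match="n_orfs"):
            simulate_genome(SimConfig(seed=0, n_chromosomes=1,
                                      chrom_length=20_000, n_orfs=60))


class TestSimulateLibrary:
    def test_full_suppression_empties_essential_interiors(self):
        cfg = small_config(essential_suppression=0.0, fringe_bp=0)
        genome, orfs, truth = simulate_genome(cfg)
        lib, _ = simulate_library(genome, orfs, truth.labels, cfg)
        for orf in orfs:
            if truth.labels[orf.orf_id] == "essential":
                n, _ = lib.sites_in(orf.chrom, orf.start, orf.end)
                assert n == 0

    def test_fringe_relaxes_five_prime_end(self):
        cfg = small_config(seed=3, essential_suppression=0.0, fringe_bp=35,
                           n_insertions=20_000)
        genome, orfs, truth = simulate_genome(cfg)
        lib, _ = simulate_library(genome, orfs, truth.labels, cfg)
        inside_fringe = inside_body = 0
        for orf in orfs:
            if truth.labels[orf.orf_id] != "essential":
                continue
            if orf.strand == "+":
                f, _ = lib.sites_in(orf.chrom, orf.start, orf.start + 35)
                b, _ = lib.sites_in(orf.chrom, orf.start + 35, orf.end)
            else:
                f, _ = lib.sites_in(orf.chrom, orf.end - 35, orf.end)
                b, _ = lib.sites_in(orf.chrom, orf.start, orf.end - 35)
            inside_fringe += f
            inside_body += b
        assert inside_body == 0
        assert inside_fringe > 0

    def test_pb_like_sites_confined_to_ttaa_spans(self):
        cfg = small_config(seed=2, transposon="pb_like", n_insertions=300)
        genome, orfs, truth = simulate_genome(cfg)
        lib, _ = simulate_library(genome, orfs, truth.labels, cfg)
        index = scan_target_sites(genome, MOTIFS["TTAA"])
        starts = index.positions["chrI"]
        for _, pos, _ in lib:
            i = np.searchsorted(starts, pos, side="right") - 1
            assert i >= 0 and starts[i] > pos - 4

    def test_pb_like_capacity_error(self):
        cfg = small_config(transposon="pb_like", n_insertions=10**6)
        genome, orfs, truth = simulate_genome(cfg)
        with pytest.raises(ValueError, match="capacity"):
            simulate_library(genome, orfs, truth.labels, cfg)

    def test_donor_proximity_bias(self):
        ratios = []
        for seed in (0, 1, 2):
            cfg = SimConfig(seed=seed, n_chromosomes=2, chrom_length=200_000,
                            n_orfs=50, n_insertions=20_000, jackpot_rate=0.0,
                            donor="chromosomal", donor_chrom="chrI",
                            donor_pos=100_000, donor_decay_bp=50_000,
                            donor_bias=10.0)
            genome, orfs, truth = simulate_genome(cfg)
            lib, _ = simulate_library(genome, orfs, truth.labels, cfg)
            near, _ = lib.sites_in("chrI", 50_000, 150_000)
            density_near = near / 100_000
            density_genome = lib.unique_insertions / genome.total_length
            ratios.append(density_near / density_genome)
        assert all(r > 2 for r in ratios)

    def test_read_counts_overdispersed(self):
        cfg = small_config(seed=5, n_insertions=10_000)
        genome, orfs, truth = simulate_genome(cfg)
        lib, _ = simulate_library(genome, orfs, truth.labels, cfg)
        counts = lib.all_counts()
        assert counts.min() >= 1
        # gamma-Poisson with k=0.5: CV ~ 1.4, an order beyond Poisson's 0.1
        assert counts.std() > counts.mean()

    def test_jackpots_recorded_and_extreme(self):
        cfg = small_config(seed=8, jackpot_rate=2.0)
        genome, orfs, truth = simulate_genome(cfg)
        lib, truth = simulate_library(genome, orfs, truth.labels, cfg)
        mean = lib.all_counts().mean()
        for chrom, pos, count in truth.jackpot_sites:
            n, reads = lib.sites_in(chrom, pos, pos + 1)
            assert n == 1 and reads == count
            assert count >= 1000 * cfg.read_mean  # low end of the multiplier range

    def test_deterministic_given_seed(self):
        cfg = small_config(seed=4)
        genome, orfs, truth = simulate_genome(cfg)
        lib1, _ = simulate_library(genome, orfs, truth.labels, cfg)
        lib2, _ = simulate_library(genome, orfs, truth.labels, cfg)
        assert list(lib1) == list(lib2)


class TestEmitReads:
    def test_single_site_round_trip(self):
        cfg = small_config()
        genome, orfs, truth = simulate_genome(cfg)
        from tnsight.calling import InsertionLibrary

        lib = InsertionLibrary.from_records([("chrI", 3000, 5)])
        spec = TrimSpec(tag_sequence="TTGGTTACGCAG", min_overlap=6)
        reads = emit_reads(lib, genome, spec, read_length=60, seed=1)
        assert len(reads) == 5
        trimmed, _ = trim_reads([s for _, s in reads], spec)
        aligned = naive_exact_mapper(genome, trimmed)
        called = call_insertions(aligned, mapq_min=20)
        assert list(called) == [("chrI", 3000, 5)]

    def test_reverse_strand_reads_collapse_to_same_site(self):
        cfg = small_config(seed=6)
        genome, orfs, truth = simulate_genome(cfg)
        from tnsight.calling import InsertionLibrary

        lib = InsertionLibrary.from_records([("chrI", 10_000, 20)])
        spec = TrimSpec(tag_sequence="TTGGTTACGCAG", min_overlap=6)
        reads = emit_reads(lib, genome, spec, read_length=60, seed=2)
        strands = {rid.split(":")[-1] for rid, _ in reads}
        assert strands == {"+", "-"}  # both orientations emitted
        trimmed, _ = trim_reads([s for _, s in reads], spec)
        called = call_insertions(naive_exact_mapper(genome, trimmed))
        assert list(called) == [("chrI", 10_000, 20)]

    def test_duplicated_segment_lost_in_round_trip(self):
        from tnsight.calling import InsertionLibrary
        from tnsight.genome import Genome

        rng = np.random.default_rng(12)
        core = "".join("ACGT"[i] for i in rng.integers(0, 4, size=5000))
        dup = core[1000:1600]
        genome = Genome({"chrI": core, "chrII": "".join(
            "ACGT"[i] for i in rng.integers(0, 4, size=2000)) + dup})
        lib = InsertionLibrary.from_records([("chrI", 1200, 3), ("chrI", 4000, 3)])
        spec = TrimSpec(tag_sequence="TTGGTTACGCAG", min_overlap=6)
        reads = emit_reads(lib, genome, spec, read_length=60, seed=3)
        trimmed, _ = trim_reads([s for _, s in reads], spec)
        called = call_insertions(naive_exact_mapper(genome, trimmed), mapq_min=20)
        assert list(called) == [("chrI", 4000, 3)]  # duplicated site filtered


class TestFixture:
    def test_manifest_reproducible(self, tmp_path):
        cfg = small_config(seed=11)
        m1 = write_fixture(tmp_path / "a", cfg)
        m2 = write_fixture(tmp_path / "b", cfg)
        assert m1["files"] == m2["files"]
        assert json.loads((tmp_path / "a" / "manifest.json").read_text())[
            "seed"] == 11

    def test_fixture_files_parse_back(self, tmp_path):
        from tnsight.calling import InsertionLibrary
        from tnsight.genome import read_fasta, read_gff

        cfg = small_config(seed=12)
        write_fixture(tmp_path / "fx", cfg)
        genome = read_fasta(tmp_path / "fx" / "genome.fasta")
        orfs = read_gff(tmp_path / "fx" / "orfs.gff3", feature_types=("gene",))
        lib = InsertionLibrary.from_tsv(tmp_path / "fx" / "insertions.tsv")
        assert genome.total_length == cfg.chrom_length * cfg.n_chromosomes
        assert len(orfs) == cfg.n_orfs
        assert lib.unique_insertions == cfg.n_insertions
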