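"""Aligner tests: seed index, triage rules, brute-force oracle equivalence,
pigeonhole completeness and statistics accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from supscan import ReferenceGenome, Read, SimulationConfig
from supscan.align import (
    align_read,
    align_readset,
    brute_force_align,
    build_index,
    compute_depth,
)
from supscan.annotate import reverse_complement
from supscan.models import AlignmentStats, ParameterError
from supscan.synthdata import simulate_reads


def _random_genome(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestSeedIndex:
    def test_kmer_positions_enumerated(self):
        ref = ReferenceGenome(id="r", sequence="ACGTACGT")
        idx = build_index(ref, k=4, read_length=12, max_mismatch=2)
        assert idx.lookup("ACGT") == [0, 4]  # 1-based positions 1 and 5

    def test_total_indexed_positions(self, rng):
        ref = ReferenceGenome(id="r", sequence=_random_genome(rng, 500))
        idx = build_index(ref, k=12)
        assert idx.n_positions == 500 - 12 + 1

    def test_seed_too_long_for_pigeonhole_raises(self, rng):
        ref = ReferenceGenome(id="r", sequence=_random_genome(rng, 100))
        with pytest.raises(ParameterError):
            build_index(ref, k=13, read_length=36, max_mismatch=2)
        with pytest.raises(ParameterError):
            build_index(ref, k=0)


class TestAlignRead:
    @pytest.fixture()
    def genome(self, rng):
        ref = ReferenceGenome(id="r", sequence=_random_genome(rng, 3_000))
        return ref, build_index(ref)

    def test_exact_substring_aligns_with_zero_mismatches(self, genome):
        ref, idx = genome
        a = align_read(ref.sequence[100:136], idx, ref)
        assert (a.status, a.position, a.strand, a.mismatches) == ("aligned", 101, "+", 0)

    def test_reverse_complement_read_aligns_on_minus_strand(self, genome):
        ref, idx = genome
        a = align_read(reverse_complement(ref.sequence[100:136]), idx, ref)
        assert (a.status, a.position, a.strand) == ("aligned", 101, "-")

    def test_read_from_duplicated_segment_is_suppressed(self, rng):
        dup = _random_genome(rng, 100)
        seq = _random_genome(rng, 400) + dup + _random_genome(rng, 300) + dup
        ref = ReferenceGenome(id="r", sequence=seq)
        idx = build_index(ref)
        a = align_read(dup[10:46], idx, ref)
        assert a.status == "suppressed"

    def test_three_substitutions_orphan(self, genome):
        ref, idx = genome
        read = list(ref.sequence[200:236])
        for i in (3, 17, 30):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        a = align_read("".join(read), idx, ref)
        assert a.status == "orphan"

    def test_non_acgt_read_is_orphaned_not_raised(self, genome):
        ref, idx = genome
        a = align_read("N" * 36, idx, ref)
        assert a.status == "orphan"

    def test_unique_best_hit_beats_secondary_two_mismatch_hit(self, rng):
        # a segment and a 2-mismatch copy: best tier has one placement
        seg = _random_genome(rng, 36)
        copy = list(seg)
        copy[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[5]]
        copy[20] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[20]]
        seq = _random_genome(rng, 200) + seg + _random_genome(rng, 200) + "".join(copy)
        ref = ReferenceGenome(id="r", sequence=seq)
        idx = build_index(ref)
        a = align_read(seg, idx, ref)
        assert (a.status, a.position, a.mismatches) == ("aligned", 201, 0)


class TestOracleEquivalence:
    def test_matches_exhaustive_hamming_search(self, rng):
        """Seed-and-extend triage equals the all-positions, both-strands
        scan for every simulated read on a small genome."""
        ref = ReferenceGenome(id="r", sequence=_random_genome(rng, 2_000))
        idx = build_index(ref)
        cfg = SimulationConfig(
            genome_length=2_000, gene_count=0, trna_count=0, mean_depth=10.0,
            error_rate=0.04, seed=3,  # high error: exercises 0-3+ mismatches
        )
        reads = simulate_reads(ref.sequence, cfg, seed=3)
        assert len(reads) >= 500
        statuses = set()
        for r in reads:
            fast = align_read(r, idx, ref)
            slow = brute_force_align(r.sequence, ref)
            assert (fast.status, fast.position, fast.strand, fast.mismatches) == (
                slow.status, slow.position, slow.strand, slow.mismatches,
            )
            statuses.add(fast.status)
        assert "aligned" in statuses and "orphan" in statuses

    @settings(max_examples=60, derandomize=True)
    @given(
        pos=st.integers(0, 1_964),
        n_mut=st.integers(0, 2),
        data=st.data(),
    )
    def test_pigeonhole_recovers_any_read_within_budget(self, pos, n_mut, data):
        """Any read within the mismatch budget of some locus is never an
        orphan: one of its three 12-mers must match there exactly."""
        rng = np.random.default_rng(99)
        genome = _random_genome(rng, 2_000)
        ref = ReferenceGenome(id="r", sequence=genome)
        idx = build_index(ref)
        read = list(genome[pos : pos + 36])
        sites = data.draw(
            st.lists(st.integers(0, 35), min_size=n_mut, max_size=n_mut, unique=True)
        )
        for i in sites:
            read[i] = data.draw(st.sampled_from([b for b in "ACGT" if b != read[i]]))
        a = align_read("".join(read), idx, ref)
        assert a.status != "orphan"
        if a.status == "aligned":
            assert a.mismatches <= len(sites)


class TestReadsetStats:
    def test_conservation_and_percentages(self, rng):
        ref = ReferenceGenome(id="r", sequence=_random_genome(rng, 2_000))
        idx = build_index(ref)
        cfg = SimulationConfig(
            genome_length=2_000, gene_count=0, trna_count=0, mean_depth=5.0,
            error_rate=0.03, seed=8,
        )
        reads = simulate_reads(ref.sequence, cfg, seed=8)
        _, stats = align_readset(reads, idx, ref)
        assert (
            stats.aligned_reads + stats.suppressed_reads + stats.orphan_reads
            == stats.total_reads
        )
        assert stats.aligned_pct + stats.suppressed_pct + stats.orphan_pct == (
            pytest.approx(100.0, abs=0.02)
        )

    def test_all_aligned_readset(self, rng):
        ref = ReferenceGenome(id="r", sequence=_random_genome(rng, 2_000))
        idx = build_index(ref)
        reads = [
            Read(f"r{i}", ref.sequence[i * 30 : i * 30 + 36], "I" * 36)
            for i in range(20)
        ]
        _, stats = align_readset(reads, idx, ref)
        assert stats.aligned_pct == 100.00
        assert stats.orphan_pct == 0.00

    def test_empty_readset_reports_zero_percentages(self, rng):
        ref = ReferenceGenome(id="r", sequence=_random_genome(rng, 500))
        idx = build_index(ref)
        _, stats = align_readset([], idx, ref)
        assert stats.total_reads == 0
        assert stats.aligned_pct == stats.orphan_pct == 0.00


class TestDepth:
    def test_depth_identity(self):
        stats = AlignmentStats.from_counts(41_667, 41_667, 0, 0, 36, 50_000)
        assert compute_depth(stats, 36, 50_000) == 30

    def test_zero_aligned_reads(self):
        stats = AlignmentStats.from_counts(10, 0, 0, 10, 36, 50_000)
        assert compute_depth(stats, 36, 50_000) == 0
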