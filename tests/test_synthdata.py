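"""Simulator unit and property tests: genome structure, truth consistency,
effect consistency, and read provenance."""

import numpy as np
import pytest

from supscan import ALL_STRAINS, SimulationConfig
from supscan.annotate import annotate_variant, reverse_complement, translate_codon
from supscan.models import SizingError
from supscan.synthdata import (
    UniqueSpec,
    generate_reference,
    implant_variants,
    n_reads_for,
    simulate_reads,
)

STANDARD_STOPS = {"TAA", "TGA", "TAG"}


def _coding_sequence(ref, feat):
    seg = ref.sequence[feat.start - 1 : feat.end]
    return seg if feat.strand == "+" else reverse_complement(seg)


class TestGenerateReference:
    def test_genome_length_and_feature_counts(self):
        cfg = SimulationConfig(genome_length=50_000, gene_count=20, trna_count=1, seed=1)
        ref, feats = generate_reference(cfg)
        assert ref.length == 50_000
        assert len(feats.cds) == 20
        assert len(feats.trnas) == 1

    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(genome_length=20_000, gene_count=6, trna_count=1, seed=5)
        ref1, feats1 = generate_reference(cfg)
        ref2, feats2 = generate_reference(cfg)
        assert ref1.sequence == ref2.sequence
        assert list(feats1) == list(feats2)

    def test_oversized_gene_request_raises_sizing_error(self):
        cfg = SimulationConfig(genome_length=5_000, gene_count=50, trna_count=0, seed=0)
        with pytest.raises(SizingError):
            generate_reference(cfg)

    def test_cds_structure_start_stop_and_frame(self, tiny_reference):
        ref, feats = tiny_reference
        for feat in feats.cds:
            coding = _coding_sequence(ref, feat)
            assert len(coding) % 3 == 0
            assert coding.startswith("ATG")
            assert coding[-3:] in STANDARD_STOPS
            # no internal in-frame stop
            internal = [coding[i : i + 3] for i in range(3, len(coding) - 3, 3)]
            assert not (set(internal) & STANDARD_STOPS)

    def test_features_non_overlapping_with_gaps(self, tiny_reference):
        _, feats = tiny_reference
        ordered = list(feats)
        for a, b in zip(ordered, ordered[1:]):
            assert a.end < b.start

    def test_exactly_one_cga_anticodon_trna(self):
        cfg = SimulationConfig(
            genome_length=30_000, gene_count=5, trna_count=3, n_strains=2, seed=3
        )
        ref, feats = generate_reference(cfg)
        cga = [
            f
            for f in feats.trnas
            if ref.sequence[
                f.start + f.anticodon_offset - 1 : f.start + f.anticodon_offset + 2
            ]
            == "CGA"
        ]
        assert len(cga) == 1


class TestImplantVariants:
    @pytest.fixture()
    def implanted(self, tiny_reference):
        ref, feats = tiny_reference
        unique = {
            "s1": UniqueSpec("SNV", "missense"),
            "s2": UniqueSpec("DEL", del_length=3),
        }
        genomes, truth = implant_variants(
            ref, feats, ("missense", "synonymous", "anticodon"), unique, seed=11
        )
        return ref, feats, genomes, truth

    def test_truth_consistency_ref_and_alt(self, implanted):
        ref, _, genomes, truth = implanted
        for t in truth:
            assert ref.base(t.position) == t.ref_allele
            if t.variant_kind != "SNV":
                continue
            carriers = genomes if t.strain_id == ALL_STRAINS else {t.strain_id: genomes[t.strain_id]}
            for sid, g in carriers.items():
                # deletions in s2 shift coordinates only downstream of the cut
                dels = [
                    d for d in truth
                    if d.variant_kind == "DEL" and d.strain_id == sid and d.position < t.position
                ]
                shift = sum(d.del_length for d in dels)
                assert g[t.position - 1 - shift] == t.alt_allele

    def test_effect_consistency_with_annotator(self, implanted):
        ref, feats, _, truth = implanted
        for t in truth:
            if t.variant_kind != "SNV":
                continue
            eff = annotate_variant(t.position, t.ref_allele, t.alt_allele, feats, ref)
            assert eff.effect_class == t.intended_effect

    def test_deletion_rows_shrink_genome(self, implanted):
        ref, _, genomes, truth = implanted
        (d,) = [t for t in truth if t.variant_kind == "DEL"]
        assert d.strain_id == "s2" and d.del_length == 3
        assert len(genomes["s2"]) == ref.length - 3
        assert len(genomes["s1"]) == ref.length

    def test_variants_spaced_at_least_one_read_length(self, implanted):
        _, _, _, truth = implanted
        positions = sorted(t.position for t in truth)
        assert min(b - a for a, b in zip(positions, positions[1:])) >= 36

    def test_anticodon_request_yields_cga_to_cta(self, implanted):
        ref, feats, _, truth = implanted
        (t,) = [x for x in truth if x.intended_effect == "anticodon_change"]
        feat = feats.covering(t.position)
        assert feat.kind == "tRNA"
        ac_start = feat.start + feat.anticodon_offset
        ac = list(ref.sequence[ac_start - 1 : ac_start + 2])
        assert "".join(ac) == "CGA"
        ac[t.position - ac_start] = t.alt_allele
        assert "".join(ac) == "CTA"

    def test_stop_gain_request_creates_stop_codon(self, tiny_reference):
        ref, feats = tiny_reference
        genomes, truth = implant_variants(
            ref, feats, ("stop_gain",), {"s1": UniqueSpec("SNV", "missense")}, seed=2
        )
        (t,) = [x for x in truth if x.intended_effect.startswith("stop_gain")]
        eff = annotate_variant(t.position, t.ref_allele, t.alt_allele, feats, ref)
        assert eff.alt_aa == "*"
        assert eff.notation.endswith(("Stop", "Amber"))


class TestSimulateReads:
    def test_read_count_follows_coverage_identity(self):
        cfg = SimulationConfig(genome_length=50_000, mean_depth=30.0, seed=0)
        assert n_reads_for(cfg, 50_000) == 41_667

    def test_zero_error_reads_are_exact_substrings(self, tiny_reference):
        ref, _ = tiny_reference
        cfg = SimulationConfig(
            genome_length=4_000, gene_count=3, trna_count=1, mean_depth=3.0,
            error_rate=0.0, seed=9,
        )
        reads = simulate_reads(ref.sequence, cfg, seed=9, strain_id="s")
        fwd = ref.sequence
        rev = reverse_complement(ref.sequence)
        for r in reads:
            assert r.sequence in fwd or r.sequence in rev

    def test_read_provenance_matches_recorded_origin(self, tiny_reference):
        ref, _ = tiny_reference
        cfg = SimulationConfig(
            genome_length=4_000, gene_count=3, trna_count=1, mean_depth=2.0,
            error_rate=0.0, seed=4,
        )
        for r in simulate_reads(ref.sequence, cfg, seed=4, strain_id="s"):
            _, _, start, strand = r.read_id.split("|")
            origin = ref.sequence[int(start) - 1 : int(start) - 1 + 36]
            expected = origin if strand == "+" else reverse_complement(origin)
            assert r.sequence == expected

    def test_mean_depth_close_to_configured(self, rng):
        # coverage identity: mean per-base depth = n_reads * read_length / L
        cfg = SimulationConfig(
            genome_length=5_000, gene_count=2, trna_count=0, mean_depth=30.0,
            error_rate=0.0, seed=21,
        )
        genome = "".join(rng.choice(list("ACGT"), 5_000))
        depths = np.zeros(5_000)
        n_seeds = 5
        for s in range(n_seeds):
            for r in simulate_reads(genome, cfg, seed=100 + s):
                _, _, start, _ = r.read_id.split("|")
                depths[int(start) - 1 : int(start) - 1 + 36] += 1
        mean_depth = depths.mean() / n_seeds
        assert mean_depth == pytest.approx(30.0, rel=0.05)

    def test_determinism_per_seed(self, tiny_reference):
        ref, _ = tiny_reference
        cfg = SimulationConfig(
            genome_length=4_000, gene_count=3, trna_count=1, mean_depth=2.0, seed=6
        )
        r1 = simulate_reads(ref.sequence, cfg, seed=6)
        r2 = simulate_reads(ref.sequence, cfg, seed=6)
        assert r1 == r2


def test_genetic_code_totality():
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    translated = {c: translate_codon(c) for c in codons}
    assert len(translated) == 64
    stops = {c for c, aa in translated.items() if aa == "*"}
    assert stops == STANDARD_STOPS
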