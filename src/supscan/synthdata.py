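"""Synthetic resequencing data: toy annotated genomes, implanted variants
with known effects, and error-bearing 36-nt single-end reads.

The generator emulates the structure of a multi-strain suppressor hunt in
a clonal bacterium: every strain genome carries an identical set of
*shared* (parental) variants relative to the reference, plus at most one
strain-*private* variant — either an SNV (the suppressor-candidate
analogue) or a small deletion, which an SNV-only caller is blind to.

All randomness flows from one integer seed: the reference uses the seed
itself, per-strain read simulation uses ``seed + strain_index`` (1-based),
and variant implanting uses ``seed + n_strains + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import annotate
from ._seq import decode, encode
from .models import (
    ALL_STRAINS,
    EffectConstructionError,
    Feature,
    FeatureTable,
    Read,
    ReferenceGenome,
    SimulationConfig,
    SizingError,
    TruthVariant,
)

#: minimum intergenic gap between placed features (bases)
MIN_GAP = 60
#: implanted variants are kept at least this far from the genome ends
END_MARGIN = 50

_STOPS = ("TAA", "TGA", "TAG")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

TRNA_SPAN = 76
ANTICODON_OFFSET = 34  # 0-based offset of the anticodon within the tRNA span


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n)
    return "".join(_SENSE_CODONS[i] for i in idx)


def generate_reference(config: SimulationConfig) -> tuple[ReferenceGenome, FeatureTable]:
    """Build a toy genome with non-overlapping CDS and tRNA features.

    Every CDS starts with ATG and ends with a stop codon on its coding
    strand; exactly one tRNA carries the anticodon CGA (the serine-tRNA
    analogue whose CGA→CTA mutation creates an amber suppressor). Raises
    :class:`SizingError` when the requested features cannot fit.
    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_feat = config.gene_count + config.trna_count
    # CDS total codon count incl. start and stop: 100..300 -> 300..900 nt
    cds_codons = rng.integers(100, 301, size=config.gene_count)
    spans = [int(c) * 3 for c in cds_codons] + [TRNA_SPAN] * config.trna_count
    total_span = sum(spans)
    min_needed = total_span + (n_feat + 1) * MIN_GAP
    if min_needed > config.genome_length:
        raise SizingError(
            f"features need >= {min_needed} bases but genome_length is "
            f"{config.genome_length}"
        )

    # shuffle which slots hold tRNAs, then distribute the slack over gaps
    kinds = ["CDS"] * config.gene_count + ["tRNA"] * config.trna_count
    order = rng.permutation(n_feat)
    slack = config.genome_length - min_needed
    extra = rng.multinomial(slack, np.full(n_feat + 1, 1.0 / (n_feat + 1)))

    # essentiality: random, but force >=2 essential and >=2 non-essential
    essential = rng.random(config.gene_count) < 0.4
    if config.gene_count >= 4:
        flat = np.flatnonzero(~essential)
        if essential.sum() < 2:
            essential[rng.choice(flat, 2 - int(essential.sum()), replace=False)] = True
        flat = np.flatnonzero(essential)
        if (~essential).sum() < 2:
            essential[rng.choice(flat, 2 - int((~essential).sum()), replace=False)] = False

    parts: list[str] = []
    features: list[Feature] = []
    pos = 0  # 0-based cursor
    cds_i = 0
    trna_i = 0
    trna_anticodons_used = 0
    for slot, fi in enumerate(order):
        gap = MIN_GAP + int(extra[slot])
        parts.append(decode(rng.integers(0, 4, size=gap).astype(np.uint8)))
        pos += gap
        kind = kinds[fi]
        if kind == "CDS":
            n_codons = int(cds_codons[cds_i])
            body = _random_codons(rng, n_codons - 2)
            stop = _STOPS[int(rng.integers(0, 2))]  # TAA or TGA
            coding = "ATG" + body + stop
            strand = "+" if rng.random() < 0.5 else "-"
            seq = coding if strand == "+" else annotate.reverse_complement(coding)
            cds_i += 1
            features.append(
                Feature(
                    feature_id=f"cds{cds_i:02d}",
                    kind="CDS",
                    start=pos + 1,
                    end=pos + len(seq),
                    strand=strand,
                    gene_name=f"gene{cds_i:02d}",
                    product="hypothetical protein",
                    essential=bool(essential[cds_i - 1]),
                )
            )
            parts.append(seq)
            pos += len(seq)
        else:
            body = decode(rng.integers(0, 4, size=TRNA_SPAN).astype(np.uint8))
            if trna_anticodons_used == 0:
                ac = "CGA"
                name = "serT"
                product = "serine tRNA (anticodon CGA)"
            else:
                ac = "CGA"
                while ac == "CGA":
                    ac = decode(rng.integers(0, 4, size=3).astype(np.uint8))
                name = f"trna{trna_i + 1:02d}"
                product = "tRNA"
            trna_anticodons_used += 1
            seq = body[:ANTICODON_OFFSET] + ac + body[ANTICODON_OFFSET + 3 :]
            trna_i += 1
            features.append(
                Feature(
                    feature_id=f"trna{trna_i:02d}",
                    kind="tRNA",
                    start=pos + 1,
                    end=pos + TRNA_SPAN,
                    strand="+",
                    gene_name=name,
                    product=product,
                    anticodon_offset=ANTICODON_OFFSET,
                )
            )
            parts.append(seq)
            pos += TRNA_SPAN

    tail = config.genome_length - pos
    parts.append(decode(rng.integers(0, 4, size=tail).astype(np.uint8)))
    genome = ReferenceGenome(id="toyref", sequence="".join(parts))
    assert genome.length == config.genome_length
    return genome, FeatureTable(features, config.genome_length)


@dataclass(frozen=True)
class UniqueSpec:
    """Requested private variant for one strain."""

    kind: str  # "SNV" | "DEL"
    effect: Optional[str] = None  # SNV only
    del_length: int = 3


def _spaced(position: int, span: int, used: list[tuple[int, int]], min_dist: int) -> bool:
    for p, s in used:
        if position < p + s + min_dist and p < position + span + min_dist:
            return False
    return True


class _Implanter:
    def __init__(
        self,
        ref: ReferenceGenome,
        features: FeatureTable,
        rng: np.random.Generator,
        read_length: int,
    ):
        self.ref = ref
        self.features = features
        self.rng = rng
        self.read_length = read_length
        self.used: list[tuple[int, int]] = []  # (position, span)
        # intergenic 1-based positions with end margins
        covered = np.zeros(ref.length + 1, dtype=bool)
        for f in features:
            covered[f.start : f.end + 1] = True
        cand = np.flatnonzero(~covered[1:]) + 1
        self.intergenic = cand[(cand > END_MARGIN) & (cand <= ref.length - END_MARGIN)]

    def _accept(self, position: int, span: int = 1) -> bool:
        if _spaced(position, span, self.used, self.read_length):
            self.used.append((position, span))
            return True
        return False

    def intergenic_snv(self) -> tuple[int, str, str]:
        for pos in self.rng.permutation(self.intergenic):
            pos = int(pos)
            if not _spaced(pos, 1, self.used, self.read_length):
                continue
            ref_b = self.ref.base(pos)
            alts = [b for b in "ACGT" if b != ref_b]
            alt = alts[int(self.rng.integers(0, 3))]
            self.used.append((pos, 1))
            return pos, ref_b, alt
        raise EffectConstructionError("no intergenic position satisfies spacing")

    def intergenic_del(self, length: int) -> tuple[int, str]:
        for pos in self.rng.permutation(self.intergenic):
            pos = int(pos)
            # deletion must sit wholly intergenic and satisfy spacing
            if pos + length - 1 > self.ref.length - END_MARGIN:
                continue
            feat_hit = any(
                self.features.covering(p) is not None for p in range(pos, pos + length)
            )
            if feat_hit or not _spaced(pos, length, self.used, self.read_length):
                continue
            self.used.append((pos, length))
            return pos, self.ref.base(pos)
        raise EffectConstructionError("no intergenic deletion site satisfies spacing")

    def cds_snv(self, requested: str) -> tuple[int, str, str, str]:
        """Find a CDS substitution realising the requested effect class.

        ``requested``: 'missense' | 'synonymous' | 'stop_gain' (any stop
        subtype, non-essential gene) | 'stop_gain_amber' (TAG, essential
        gene). Returns (position, ref, alt, realised effect_class).
        """
        if requested == "stop_gain_amber":
            pool = [f for f in self.features.cds if f.essential]
        elif requested == "stop_gain":
            pool = [f for f in self.features.cds if not f.essential]
        else:
            pool = list(self.features.cds)
        for fi in self.rng.permutation(len(pool)):
            feat = pool[int(fi)]
            # skip start and stop codons on the coding strand
            lo, hi = feat.start + 3, feat.end - 3
            positions = np.arange(lo, hi + 1)
            for pos in self.rng.permutation(positions):
                pos = int(pos)
                if pos <= END_MARGIN or pos > self.ref.length - END_MARGIN:
                    continue
                if not _spaced(pos, 1, self.used, self.read_length):
                    continue
                ref_b = self.ref.base(pos)
                alts = list(self.rng.permutation([b for b in "ACGT" if b != ref_b]))
                for alt in alts:
                    eff = annotate.codon_effect(pos, ref_b, alt, feat, self.ref)
                    if requested == "stop_gain":
                        ok = eff.effect_class.startswith("stop_gain")
                    else:
                        ok = eff.effect_class == requested
                    if ok:
                        self.used.append((pos, 1))
                        return pos, ref_b, alt, eff.effect_class
        raise EffectConstructionError(f"could not realise effect {requested!r}")

    def anticodon_snv(self) -> tuple[int, str, str]:
        for feat in self.features.trnas:
            ac_start = feat.start + feat.anticodon_offset
            ac = self.ref.sequence[ac_start - 1 : ac_start + 2]
            if ac != "CGA":
                continue
            pos = ac_start + 1  # middle base G -> T yields CTA
            if not _spaced(pos, 1, self.used, self.read_length):
                continue
            self.used.append((pos, 1))
            return pos, "G", "T"
        raise EffectConstructionError("no CGA-anticodon tRNA available")


def implant_variants(
    ref: ReferenceGenome,
    features: FeatureTable,
    shared_spec: Sequence[str],
    unique_spec: dict[str, UniqueSpec],
    seed: int,
    read_length: int = 36,
) -> tuple[dict[str, str], list[TruthVariant]]:
    """Implant shared and strain-private variants; return strain genomes + truth.

    ``shared_spec`` lists requested effect classes for the parental
    variants ('intergenic', 'synonymous', 'missense', 'stop_gain',
    'stop_gain_amber', 'anticodon'); every strain genome receives all of
    them. ``unique_spec`` maps each strain id to its private variant
    request. Implanted positions are pairwise separated by at least one
    read length; every realised effect is re-verified through the
    annotation module before the genomes are built.
    """
    rng = np.random.default_rng(seed)
    imp = _Implanter(ref, features, rng, read_length)
    truth: list[TruthVariant] = []

    def realise_snv(effect: str, strain_id: str, intended_class: str) -> TruthVariant:
        if effect == "intergenic":
            pos, ref_b, alt = imp.intergenic_snv()
            realised = "intergenic"
        elif effect == "anticodon":
            pos, ref_b, alt = imp.anticodon_snv()
            realised = "anticodon_change"
        elif effect in ("missense", "synonymous", "stop_gain", "stop_gain_amber"):
            pos, ref_b, alt, realised = imp.cds_snv(effect)
        else:
            raise EffectConstructionError(f"unknown effect request {effect!r}")
        return TruthVariant(
            strain_id=strain_id,
            position=pos,
            ref_allele=ref_b,
            alt_allele=alt,
            variant_kind="SNV",
            intended_class=intended_class,
            intended_effect=realised,
        )

    for effect in shared_spec:
        truth.append(realise_snv(effect, ALL_STRAINS, "parental"))

    for strain_id in unique_spec:  # insertion order: deterministic
        req = unique_spec[strain_id]
        if req.kind == "SNV":
            truth.append(realise_snv(req.effect, strain_id, "unique"))
        elif req.kind == "DEL":
            pos, ref_b = imp.intergenic_del(req.del_length)
            truth.append(
                TruthVariant(
                    strain_id=strain_id,
                    position=pos,
                    ref_allele=ref_b,
                    alt_allele=str(req.del_length),
                    variant_kind="DEL",
                    intended_class="unique",
                    intended_effect="intergenic",
                    del_length=req.del_length,
                )
            )
        else:
            raise EffectConstructionError(f"unknown variant kind {req.kind!r}")

    verify_truth_effects(truth, ref, features)

    # build strain genomes: all shared SNVs + own private variant
    shared = [t for t in truth if t.strain_id == ALL_STRAINS]
    genomes: dict[str, str] = {}
    for strain_id in unique_spec:
        seq = list(ref.sequence)
        for t in shared:
            seq[t.position - 1] = t.alt_allele
        own = [t for t in truth if t.strain_id == strain_id]
        deletion = None
        for t in own:
            if t.variant_kind == "SNV":
                seq[t.position - 1] = t.alt_allele
            else:
                deletion = t
        if deletion is not None:
            del seq[deletion.position - 1 : deletion.position - 1 + deletion.del_length]
        genomes[strain_id] = "".join(seq)
    return genomes, truth


def verify_truth_effects(
    truth: Sequence[TruthVariant], ref: ReferenceGenome, features: FeatureTable
) -> None:
    """Check every truth SNV against the annotation module.

    Raises :class:`EffectConstructionError` when a variant's annotated
    effect class disagrees with its intended one — the simulator and the
    annotator must be mutually consistent by construction.
    """
    for t in truth:
        if ref.base(t.position) != t.ref_allele:
            raise EffectConstructionError(
                f"truth ref allele mismatch at {t.position}"
            )
        if t.variant_kind != "SNV":
            continue
        eff = annotate.annotate_variant(
            t.position, t.ref_allele, t.alt_allele, features, ref
        )
        if eff.effect_class != t.intended_effect:
            raise EffectConstructionError(
                f"variant at {t.position} annotates as {eff.effect_class}, "
                f"intended {t.intended_effect}"
            )


def n_reads_for(config: SimulationConfig, genome_length: int) -> int:
    """round(mean_depth * genome_length / read_length), half away from zero."""
    x = config.mean_depth * genome_length / config.read_length
    return int(np.floor(x + 0.5))


def simulate_reads(
    strain_genome: str,
    config: SimulationConfig,
    seed: int,
    strain_id: str = "strain",
) -> list[Read]:
    """Uniform single-end read simulation with substitution-only errors.

    Read count is ``round(mean_depth * L / read_length)`` for the strain
    genome's own length ``L``. Each read starts uniformly over valid
    positions, is reverse-complemented with probability 1/2, and each
    base is substituted independently with probability ``error_rate`` (to
    a uniformly chosen *different* base). Qualities are constant. Read
    ids encode provenance as ``strain|index|origin_start_1based|strand``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    L = len(strain_genome)
    rl = config.read_length
    n = n_reads_for(config, L)
    codes = encode(strain_genome)

    starts = rng.integers(0, L - rl + 1, size=n)
    minus = rng.random(n) < 0.5
    mat = codes[starts[:, None] + np.arange(rl)]
    # reverse-complement the minus-strand rows
    mat[minus] = 3 - mat[minus][:, ::-1]
    if config.error_rate > 0:
        err = rng.random((n, rl)) < config.error_rate
        shift = rng.integers(1, 4, size=(n, rl), dtype=np.uint8)
        mat[err] = (mat[err] + shift[err]) % 4
    qual = "I" * rl
    reads = []
    for i in range(n):
        strand = "-" if minus[i] else "+"
        rid = f"{strain_id}|{i}|{int(starts[i]) + 1}|{strand}"
        reads.append(Read(read_id=rid, sequence=decode(mat[i]), quality=qual))
    return reads
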