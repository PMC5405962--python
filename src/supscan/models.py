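"""Core domain types shared across the pipeline stages.

Coordinates are 1-based inclusive throughout (GFF3/VCF convention);
the only 0-based quantity is ``Feature.anticodon_offset``, which is an
offset *within* a tRNA feature.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

DNA_ALPHABET = frozenset("ACGT")

#: strain label used for variants carried by every strain
ALL_STRAINS = "ALL"


class SupscanError(Exception):
    """Base class for pipeline errors."""


class SizingError(SupscanError):
    """Requested features do not fit in the genome."""


class EffectConstructionError(SupscanError):
    """A requested variant effect cannot be realised on the genome."""


class ParameterError(SupscanError):
    """Invalid aligner/caller parameter."""


class ConsistencyError(SupscanError):
    """Internal contradiction between artifacts (signals a bug upstream)."""


@dataclass(frozen=True)
class ReferenceGenome:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not set(self.sequence) <= DNA_ALPHABET:
            bad = sorted(set(self.sequence) - DNA_ALPHABET)
            raise ValueError(f"non-ACGT symbols in reference: {bad}")

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequence[position - 1]


@dataclass(frozen=True)
class Feature:
    """A CDS or tRNA gene on the toy genome.

    ``anticodon_offset`` is the 0-based offset of the 3-base anticodon
    within the feature span (tRNA only; ``None`` for CDS).
    """

    feature_id: str
    kind: str  # "CDS" | "tRNA"
    start: int
    end: int
    strand: str  # "+" | "-"
    gene_name: str
    product: str
    essential: bool = False
    anticodon_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("CDS", "tRNA"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError("feature coordinates must satisfy 1 <= start <= end")
        if self.kind == "tRNA":
            if self.anticodon_offset is None:
                raise ValueError("tRNA feature requires anticodon_offset")
            if not 0 <= self.anticodon_offset <= self.span - 3:
                raise ValueError("anticodon_offset outside tRNA span")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


class FeatureTable:
    """Non-overlapping features sorted by start coordinate."""

    def __init__(self, features: list[Feature], genome_length: int):
        feats = sorted(features, key=lambda f: f.start)
        prev_end = 0
        for f in feats:
            if f.end > genome_length:
                raise ValueError(f"feature {f.feature_id} exceeds genome length")
            if f.start <= prev_end:
                raise ValueError(f"feature {f.feature_id} overlaps its predecessor")
            prev_end = f.end
        self.features: list[Feature] = feats
        self.genome_length = genome_length
        self._starts = [f.start for f in feats]

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def covering(self, position: int) -> Optional[Feature]:
        """The unique feature covering a 1-based position, or None."""
        import bisect

        if not 1 <= position <= self.genome_length:
            raise ValueError(f"position {position} outside genome")
        i = bisect.bisect_right(self._starts, position) - 1
        if i >= 0 and self.features[i].contains(position):
            return self.features[i]
        return None

    @property
    def cds(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "CDS"]

    @property
    def trnas(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "tRNA"]


@dataclass(frozen=True)
class TruthVariant:
    """A variant implanted by the simulator (simulation ground truth).

    For SNVs ``alt_allele`` is the substituted base; for deletions it is
    the deletion length as text and ``del_length`` bases starting at
    ``position`` are removed from the strain genome.
    """

    strain_id: str  # strain label, or ALL_STRAINS for parental variants
    position: int
    ref_allele: str
    alt_allele: str
    variant_kind: str  # "SNV" | "DEL"
    intended_class: str  # "parental" | "unique"
    intended_effect: str
    del_length: int = 0

    def __post_init__(self) -> None:
        if self.variant_kind not in ("SNV", "DEL"):
            raise ValueError(f"unknown variant kind {self.variant_kind!r}")
        if self.variant_kind == "SNV":
            if self.alt_allele == self.ref_allele or self.alt_allele not in DNA_ALPHABET:
                raise ValueError("SNV alt allele must be a base differing from ref")
        elif self.del_length < 1:
            raise ValueError("DEL requires del_length >= 1")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_allele, self.alt_allele)


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic resequencing experiment.

    Defaults mirror the standard multi-strain scenario: a 50-kb toy
    genome with 20 protein-coding genes and one serine tRNA, 13 clonal
    strains, 36-nt single-end reads at 150-fold coverage with a 1e-4
    uniform per-base substitution error.
    """

    genome_length: int = 50_000
    gene_count: int = 20
    trna_count: int = 1
    n_strains: int = 13
    read_length: int = 36
    mean_depth: float = 150.0
    error_rate: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must lie in [0, 0.25)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.gene_count < 0 or self.trna_count < 0 or self.n_strains < 1:
            raise ValueError("counts must be non-negative (>=1 strain)")


@dataclass(frozen=True)
class Read:
    """A simulated single-end read with its FASTQ quality string."""

    read_id: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class AlignedRead:
    """Triage outcome for one read.

    ``position`` is the 1-based leftmost coordinate on the forward
    reference (aligned reads only); reverse-strand placements are
    recorded via ``strand``.
    """

    read_id: str
    status: str  # "aligned" | "suppressed" | "orphan"
    position: Optional[int] = None
    strand: Optional[str] = None
    mismatches: Optional[int] = None

    def __post_init__(self) -> None:
        if self.status not in ("aligned", "suppressed", "orphan"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "aligned" and (self.position is None or self.strand is None):
            raise ValueError("aligned read requires position and strand")
        if self.status == "orphan" and self.position is not None:
            raise ValueError("orphan read cannot carry a position")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.125 -> 0.13), as table percentages print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AlignmentStats:
    """Read-triage accounting for one strain (read-statistics table row)."""

    total_reads: int
    aligned_reads: int
    suppressed_reads: int
    orphan_reads: int
    aligned_pct: float
    suppressed_pct: float
    orphan_pct: float
    depth: int

    @classmethod
    def from_counts(
        cls,
        total: int,
        aligned: int,
        suppressed: int,
        orphan: int,
        read_length: int,
        genome_length: int,
    ) -> "AlignmentStats":
        if aligned + suppressed + orphan != total:
            raise ConsistencyError("aligned + suppressed + orphan != total")
        if total == 0:
            pcts = (0.0, 0.0, 0.0)
        else:
            pcts = tuple(
                round_half_up(100.0 * c / total) for c in (aligned, suppressed, orphan)
            )
        depth = int(Decimal(aligned) * read_length / genome_length + Decimal("0.5"))
        return cls(total, aligned, suppressed, orphan, *pcts, depth)


@dataclass(frozen=True)
class VariantCall:
    """A consensus SNV call in one strain."""

    strain_id: str
    position: int
    ref_allele: str
    alt_allele: str
    support_fraction: float
    depth: int

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class ClassifiedVariant:
    """Cross-strain classification of one variant key."""

    key: tuple[int, str, str]
    n_strains_present: int
    variant_class: str  # "parental" | "unique" | "shared_subset"
    carrier_strains: tuple[str, ...]


@dataclass(frozen=True)
class StrainContext:
    """Strain-global annotation state derived from the full call set."""

    strain_id: str
    amber_suppressor: bool


@dataclass(frozen=True)
class EffectAnnotation:
    """Protein-level (or tRNA/intergenic) consequence of one variant."""

    key: tuple[int, str, str]
    context: str  # "CDS" | "tRNA" | "intergenic"
    gene_name: str = "-"
    codon_number: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    effect_class: str = "intergenic"
    notation: str = "-"
    readthrough_applied: bool = False
    suppressor_trna: bool = False

    def replace(self, **kw) -> "EffectAnnotation":
        return dataclasses.replace(self, **kw)
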