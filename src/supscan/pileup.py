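"""Per-position base tallies and the >=99%-consensus SNV caller.

The caller encodes the study's acceptance rule for a mutation in a
clonal isolate: a site is called iff enough reads cover it and the most
frequent non-reference base is supported by at least ``min_fraction`` of
*all* reads piled on the position. There is no gapped logic anywhere —
strains whose private lesion is an indel simply yield no call, which is
the deliberate blindness of an SNV-only pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import encode, revcomp_codes
from .models import (
    AlignedRead,
    ConsistencyError,
    Read,
    ReferenceGenome,
    VariantCall,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_FRACTION = 0.99
DEFAULT_MIN_DEPTH = 10

_BASES = "ACGT"


@dataclass(frozen=True)
class PileupColumn:
    position: int  # 1-based
    depth: int
    base_counts: dict  # base -> count


class Pileup:
    """Dense base-count matrix over the whole reference (positions x ACGT)."""

    def __init__(self, counts: np.ndarray):
        self.counts = counts  # shape (L, 4), int32

    @property
    def genome_length(self) -> int:
        return self.counts.shape[0]

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column(self, position: int) -> PileupColumn:
        row = self.counts[position - 1]
        return PileupColumn(
            position=position,
            depth=int(row.sum()),
            base_counts={b: int(row[i]) for i, b in enumerate(_BASES) if row[i]},
        )

    def __iter__(self):
        for p in range(1, self.genome_length + 1):
            yield self.column(p)


def build_pileup(
    alignments: Sequence[AlignedRead],
    reads: Sequence[Read],
    ref: ReferenceGenome,
) -> Pileup:
    """Tally the base each aligned read places on every covered position.

    ``alignments`` and ``reads`` are parallel (one triage record per
    read, same order). Suppressed and orphan reads contribute nothing;
    reverse-strand reads contribute their reverse-complemented bases in
    reference orientation.
    """
    if len(alignments) != len(reads):
        raise ConsistencyError("alignments and reads must be parallel")
    L = ref.length
    counts = np.zeros((L, 4), dtype=np.int32)
    for aln, read in zip(alignments, reads):
        if aln.status != "aligned":
            continue
        if aln.read_id != read.read_id:
            raise ConsistencyError(
                f"alignment {aln.read_id} does not match read {read.read_id}"
            )
        codes = encode(read.sequence)
        if aln.strand == "-":
            codes = revcomp_codes(codes)
        p0 = aln.position - 1
        if p0 < 0 or p0 + len(codes) > L:
            raise ConsistencyError(
                f"alignment of {aln.read_id} at {aln.position} out of bounds"
            )
        counts[np.arange(p0, p0 + len(codes)), codes] += 1
    return Pileup(counts)


def call_snvs(
    pileup: Pileup,
    ref: ReferenceGenome,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_depth: int = DEFAULT_MIN_DEPTH,
    strain_id: str = "strain",
) -> list[VariantCall]:
    """Emit a call wherever the consensus base differs from the reference.

    A call at position p requires depth >= ``min_depth``, most frequent
    base b != reference, and count(b)/depth >= ``min_fraction``. Ties for
    the most frequent base break lexicographically (A<C<G<T) and are
    logged; with ``min_fraction`` > 0.5 a tie can never produce a call.
    Sites where the consensus equals the reference are never reported.
    """
    if not 0.5 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0.5, 1]")
    counts = pileup.counts
    depth = counts.sum(axis=1)
    top = counts.argmax(axis=1)  # argmax takes the first maximum: A<C<G<T
    top_count = np.take_along_axis(counts, top[:, None], axis=1)[:, 0]
    ref_codes = encode(ref.sequence)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, top_count / np.maximum(depth, 1), 0.0)
    mask = (depth >= min_depth) & (top != ref_codes) & (frac >= min_fraction)

    calls = []
    for p0 in np.flatnonzero(mask):
        row = counts[p0]
        if np.count_nonzero(row == row[top[p0]]) > 1:
            logger.info("tie for most frequent base at %d (no call possible "
                        "above 50%% support)", p0 + 1)
        calls.append(
            VariantCall(
                strain_id=strain_id,
                position=int(p0) + 1,
                ref_allele=_BASES[ref_codes[p0]],
                alt_allele=_BASES[top[p0]],
                support_fraction=float(top_count[p0] / depth[p0]),
                depth=int(depth[p0]),
            )
        )
    return calls
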