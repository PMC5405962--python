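"""Seed-and-extend placement of short reads on the reference.

Strategy: the read is split into ``max_mismatch + 1`` disjoint k-mers
(pigeonhole: any placement with at most ``max_mismatch`` substitutions
matches at least one seed exactly), candidate loci come from exact
k-mer lookup on both the read and its reverse complement, and every
candidate is extended to a full-length Hamming comparison against the
forward reference.

Triage follows best-hit semantics: among placements within the mismatch
budget, a unique placement at the minimum mismatch count is *aligned*,
two or more tied placements make the read *suppressed* (it maps to more
than one location), and a read with no placement within budget is an
*orphan*. Reads containing non-ACGT symbols are orphans, not errors.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from ._seq import decode, encode, revcomp_codes
from .models import (
    AlignedRead,
    AlignmentStats,
    ParameterError,
    Read,
    ReferenceGenome,
)

logger = logging.getLogger(__name__)

DEFAULT_K = 12
DEFAULT_MAX_MISMATCH = 2


class SeedIndex:
    """Exact k-mer index of the forward reference."""

    def __init__(self, ref: ReferenceGenome, k: int):
        self.k = k
        self.ref_id = ref.id
        self.genome_length = ref.length
        self.ref_codes = encode(ref.sequence)
        table: dict[str, list[int]] = {}
        seq = ref.sequence
        for i in range(ref.length - k + 1):
            table.setdefault(seq[i : i + k], []).append(i)  # 0-based starts
        self.table = table

    def lookup(self, kmer: str) -> list[int]:
        return self.table.get(kmer, [])

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.table.values())


def build_index(
    ref: ReferenceGenome,
    k: int = DEFAULT_K,
    read_length: int = 36,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> SeedIndex:
    """Index all forward k-mers of the reference.

    Requires ``(max_mismatch + 1) * k <= read_length`` so the pigeonhole
    guarantee holds for the seeding scheme.
    """
    if k < 1:
        raise ParameterError("seed length k must be >= 1")
    if (max_mismatch + 1) * k > read_length:
        raise ParameterError(
            f"k={k} too large: need (max_mismatch+1)*k <= read_length "
            f"({(max_mismatch + 1) * k} > {read_length})"
        )
    return SeedIndex(ref, k)


def _candidates(seq: str, index: SeedIndex, n_seeds: int) -> set[int]:
    """0-based candidate leftmost positions from exact seed lookup."""
    k = index.k
    L = index.genome_length
    rl = len(seq)
    cands: set[int] = set()
    for s in range(n_seeds):
        off = s * k
        for hit in index.lookup(seq[off : off + k]):
            start = hit - off
            if 0 <= start <= L - rl:
                cands.add(start)
    return cands


def align_read(
    read: Read | str,
    index: SeedIndex,
    ref: ReferenceGenome,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> AlignedRead:
    """Place one read; returns its triage status, locus, strand and
    mismatch count (see module docstring for the decision rule)."""
    if isinstance(read, Read):
        rid, seq = read.read_id, read.sequence
    else:
        rid, seq = "read", read

    if not set(seq) <= set("ACGT"):
        logger.debug("read %s contains non-ACGT symbols; orphaned", rid)
        return AlignedRead(read_id=rid, status="orphan")

    n_seeds = max_mismatch + 1
    if n_seeds * index.k > len(seq):
        raise ParameterError("read shorter than the seeding scheme requires")

    fwd = encode(seq)
    rev = revcomp_codes(fwd)
    rev_seq = decode(rev)
    g = index.ref_codes
    rl = len(seq)

    placements: list[tuple[int, int, str]] = []  # (mismatches, 0-based pos, strand)
    for strand, s, codes in (("+", seq, fwd), ("-", rev_seq, rev)):
        for pos in _candidates(s, index, n_seeds):
            mm = int(np.count_nonzero(g[pos : pos + rl] != codes))
            if mm <= max_mismatch:
                placements.append((mm, pos, strand))

    if not placements:
        return AlignedRead(read_id=rid, status="orphan")
    best = min(p[0] for p in placements)
    tier = [p for p in placements if p[0] == best]
    if len(tier) > 1:
        return AlignedRead(read_id=rid, status="suppressed", mismatches=best)
    mm, pos, strand = tier[0]
    return AlignedRead(
        read_id=rid, status="aligned", position=pos + 1, strand=strand, mismatches=mm
    )


def align_readset(
    reads: Sequence[Read],
    index: SeedIndex,
    ref: ReferenceGenome,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[list[AlignedRead], AlignmentStats]:
    """Triage every read and assemble the per-strain statistics row."""
    alignments = [align_read(r, index, ref, max_mismatch) for r in reads]
    counts = {"aligned": 0, "suppressed": 0, "orphan": 0}
    for a in alignments:
        counts[a.status] += 1
    total = len(alignments)
    if total == 0:
        logger.warning("empty read set: percentages reported as 0.00")
    rl = len(reads[0].sequence) if reads else 0
    stats = AlignmentStats.from_counts(
        total,
        counts["aligned"],
        counts["suppressed"],
        counts["orphan"],
        rl,
        ref.length,
    )
    return alignments, stats


def compute_depth(stats: AlignmentStats, read_length: int, genome_length: int) -> int:
    """Approximate fold coverage: aligned_reads * read_length / genome_length,
    rounded to the nearest integer."""
    if genome_length <= 0:
        raise ParameterError("genome_length must be positive")
    x = stats.aligned_reads * read_length / genome_length
    return int(np.floor(x + 0.5))


def brute_force_align(
    read_seq: str, ref: ReferenceGenome, max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> AlignedRead:
    """Exhaustive all-positions, both-strands Hamming search.

    Independent oracle for :func:`align_read`; quadratic, intended for
    genomes of a few kilobases only.
    """
    from .annotate import reverse_complement

    if not set(read_seq) <= set("ACGT"):
        return AlignedRead(read_id="read", status="orphan")
    g = encode(ref.sequence)
    rl = len(read_seq)
    if rl > ref.length:
        return AlignedRead(read_id="read", status="orphan")
    windows = np.lib.stride_tricks.sliding_window_view(g, rl)
    placements = []
    for strand, seq in (("+", read_seq), ("-", reverse_complement(read_seq))):
        mms = (windows != encode(seq)).sum(axis=1)
        for pos in np.flatnonzero(mms <= max_mismatch):
            placements.append((int(mms[pos]), int(pos), strand))
    if not placements:
        return AlignedRead(read_id="read", status="orphan")
    best = min(p[0] for p in placements)
    tier = [p for p in placements if p[0] == best]
    if len(tier) > 1:
        return AlignedRead(read_id="read", status="suppressed", mismatches=best)
    mm, pos, strand = tier[0]
    return AlignedRead(
        read_id="read", status="aligned", position=pos + 1, strand=strand, mismatches=mm
    )
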