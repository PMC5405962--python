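"""Cross-strain combination of call sets and parental/unique classification.

A variant present in every sequenced strain is *parental* — a difference
between the lab parent and the public reference, not a suppressor. A
variant present in exactly one strain is *unique*, the suppressor
candidate for that strain. Anything in between (``shared_subset``) is
anomalous under the clonal single-suppressor model and is flagged, never
silently dropped.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import pandas as pd

from .models import ALL_STRAINS, ClassifiedVariant, ConsistencyError, TruthVariant, VariantCall

logger = logging.getLogger(__name__)


class VariantMatrix:
    """Boolean presence of each (position, ref, alt) key in each strain."""

    def __init__(self, presence: pd.DataFrame):
        self.presence = presence  # index: MultiIndex (position, ref, alt); cols: strains

    @property
    def strains(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def keys(self) -> list[tuple[int, str, str]]:
        return [tuple(k) for k in self.presence.index]

    def __len__(self) -> int:
        return len(self.presence)


def build_matrix(call_sets: dict[str, Sequence[VariantCall]]) -> VariantMatrix:
    """Union of call keys across strains as a variants-by-strains table.

    Two strains reporting different reference alleles at one position
    indicate a simulator or caller bug and raise ConsistencyError.
    """
    if len(call_sets) < 2:
        raise ValueError("need call sets for at least 2 strains")
    ref_at: dict[int, str] = {}
    for strain, calls in call_sets.items():
        for c in calls:
            prev = ref_at.setdefault(c.position, c.ref_allele)
            if prev != c.ref_allele:
                raise ConsistencyError(
                    f"strains disagree on reference allele at {c.position}: "
                    f"{prev} vs {c.ref_allele}"
                )
    keys = sorted({c.key for calls in call_sets.values() for c in calls})
    strains = list(call_sets)
    index = pd.MultiIndex.from_tuples(keys, names=["position", "ref", "alt"])
    presence = pd.DataFrame(False, index=index, columns=strains)
    for strain, calls in call_sets.items():
        for c in calls:
            presence.loc[c.key, strain] = True
    return VariantMatrix(presence)


def classify_variants(matrix: VariantMatrix) -> list[ClassifiedVariant]:
    """Label every key parental (all strains), unique (one strain) or
    shared_subset (anything between; logged as anomalous)."""
    n_total = len(matrix.strains)
    out = []
    for key, row in matrix.presence.iterrows():
        carriers = tuple(s for s in matrix.strains if row[s])
        n = len(carriers)
        if n == n_total:
            cls = "parental"
        elif n == 1:
            cls = "unique"
        else:
            cls = "shared_subset"
            logger.warning(
                "variant %s present in %d/%d strains: anomalous under the "
                "single-suppressor model, flagged for review", key, n, n_total
            )
        out.append(
            ClassifiedVariant(
                key=tuple(key),
                n_strains_present=n,
                variant_class=cls,
                carrier_strains=carriers,
            )
        )
    return out


def summarize(
    classified: Sequence[ClassifiedVariant],
    strains: Sequence[str],
    truth: Optional[Sequence[TruthVariant]] = None,
) -> dict:
    """Class counts, per-strain unique-call counts and (with truth)
    recovery metrics.

    Sensitivity/precision are computed per class over SNV truth only —
    deletions are invisible to the caller by design and are listed
    separately as expected-blind strains.
    """
    class_counts = {"parental": 0, "unique": 0, "shared_subset": 0}
    per_strain_unique: dict[str, int] = {s: 0 for s in strains}
    for cv in classified:
        class_counts[cv.variant_class] += 1
        if cv.variant_class == "unique":
            per_strain_unique[cv.carrier_strains[0]] += 1

    report = {
        "class_counts": class_counts,
        "per_strain_unique": per_strain_unique,
        "strains_with_one_unique": sum(
            1 for v in per_strain_unique.values() if v == 1
        ),
        "strains_with_zero_unique": sum(
            1 for v in per_strain_unique.values() if v == 0
        ),
    }

    if truth is not None:
        truth_snv = [t for t in truth if t.variant_kind == "SNV"]
        truth_parental = {t.key for t in truth_snv if t.strain_id == ALL_STRAINS}
        truth_unique = {t.key for t in truth_snv if t.strain_id != ALL_STRAINS}
        found = {
            "parental": {cv.key for cv in classified if cv.variant_class == "parental"},
            "unique": {cv.key for cv in classified if cv.variant_class == "unique"},
        }
        recovery = {}
        for cls, truth_keys in (("parental", truth_parental), ("unique", truth_unique)):
            tp = len(found[cls] & truth_keys)
            sens = tp / len(truth_keys) if truth_keys else float("nan")
            prec = tp / len(found[cls]) if found[cls] else float("nan")
            recovery[cls] = {"sensitivity": sens, "precision": prec}
        report["recovery"] = recovery
        report["expected_blind_strains"] = sorted(
            t.strain_id for t in truth if t.variant_kind == "DEL"
        )
    return report
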