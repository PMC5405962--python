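"""Variant-effect annotation: feature localisation, codon consequences,
tRNA anticodon logic and amber-suppressor readthrough.

Effect notation follows the compact dialect used in resequencing reports
of clonal bacterial isolates rather than HGVS: ``L36Q`` for a missense
change, ``E38E`` for a synonymous one, ``W286Stop`` for a premature stop.
A stop gain that creates the amber codon (TAG) inside an *essential* gene
is written ``Q11Amber``; when the strain additionally carries the
anticodon CGA→CTA serine-tRNA variant (an amber suppressor, which reads
TAG and misincorporates serine) the notation gains the suffix ``(S)``:
``Q11Amber(S)``.
"""

from __future__ import annotations

from typing import Iterable, Optional

from Bio.Seq import Seq

from .models import (
    ConsistencyError,
    EffectAnnotation,
    Feature,
    FeatureTable,
    ReferenceGenome,
    StrainContext,
    VariantCall,
)

STOP_SUBTYPE = {"TAG": "amber", "TAA": "ochre", "TGA": "opal"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Single-letter amino acid for a codon; '*' for a stop (bacterial code)."""
    return str(Seq(codon).translate(table=11))


def locate(position: int, features: FeatureTable) -> tuple[str, Optional[Feature]]:
    """Classify a genome position as (context, feature).

    Returns ``("CDS", feature)``, ``("tRNA", feature)`` or
    ``("intergenic", None)``.
    """
    feat = features.covering(position)
    if feat is None:
        return ("intergenic", None)
    return (feat.kind, feat)


def _aa_label(aa: str) -> str:
    return "Stop" if aa == "*" else aa


def codon_effect(
    position: int,
    ref_allele: str,
    alt_allele: str,
    feature: Feature,
    ref: ReferenceGenome,
) -> EffectAnnotation:
    """Consequence of a single-base substitution inside a CDS.

    The codon is read on the coding strand: for a minus-strand gene the
    feature span is reverse-complemented and the forward-strand alleles
    are complemented before translation.
    """
    if feature.kind != "CDS":
        raise ValueError("codon_effect requires a CDS feature")
    if not feature.contains(position):
        raise ValueError("position outside feature span")
    if ref.base(position) != ref_allele:
        raise ConsistencyError(
            f"ref allele {ref_allele} does not match genome "
            f"{ref.base(position)} at {position}"
        )

    segment = ref.sequence[feature.start - 1 : feature.end]
    if feature.strand == "+":
        coding = segment
        offset = position - feature.start
        coding_alt = alt_allele
    else:
        coding = reverse_complement(segment)
        offset = feature.end - position
        coding_alt = alt_allele.translate(_COMPLEMENT)

    codon_number = offset // 3 + 1
    codon_pos = offset % 3
    ref_codon = coding[3 * (codon_number - 1) : 3 * codon_number]
    alt_codon = ref_codon[:codon_pos] + coding_alt + ref_codon[codon_pos + 1 :]

    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)

    if alt_aa == "*" and ref_aa != "*":
        effect_class = f"stop_gain_{STOP_SUBTYPE[alt_codon]}"
        if alt_codon == "TAG" and feature.essential:
            alt_label = "Amber"
        else:
            alt_label = "Stop"
    elif alt_aa == ref_aa:
        effect_class = "synonymous"
        alt_label = _aa_label(alt_aa)
    else:
        effect_class = "missense"
        alt_label = _aa_label(alt_aa)

    notation = f"{_aa_label(ref_aa)}{codon_number}{alt_label}"
    return EffectAnnotation(
        key=(position, ref_allele, alt_allele),
        context="CDS",
        gene_name=feature.gene_name,
        codon_number=codon_number,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect_class=effect_class,
        notation=notation,
    )


def anticodon_effect(
    position: int,
    ref_allele: str,
    alt_allele: str,
    feature: Feature,
    ref: ReferenceGenome,
) -> EffectAnnotation:
    """Consequence of a substitution inside a tRNA gene.

    tRNA features are stored so that the anticodon reads directly on the
    forward strand. A CGA→CTA anticodon change converts the serine tRNA
    into an amber suppressor (CTA pairs with the TAG stop codon); any
    other anticodon change, and any tRNA-body change, carries no
    suppressor flag.
    """
    if feature.kind != "tRNA":
        raise ValueError("anticodon_effect requires a tRNA feature")
    if ref.base(position) != ref_allele:
        raise ConsistencyError("ref allele mismatch at tRNA position")

    ac_start = feature.start + feature.anticodon_offset  # 1-based
    ac_end = ac_start + 2
    key = (position, ref_allele, alt_allele)
    if not ac_start <= position <= ac_end:
        return EffectAnnotation(
            key=key,
            context="tRNA",
            gene_name=feature.gene_name,
            effect_class="trna_body",
            notation="-",
        )

    ref_ac = ref.sequence[ac_start - 1 : ac_end]
    i = position - ac_start
    alt_ac = ref_ac[:i] + alt_allele + ref_ac[i + 1 :]
    suppressor = ref_ac == "CGA" and alt_ac == "CTA"
    return EffectAnnotation(
        key=key,
        context="tRNA",
        gene_name=feature.gene_name,
        effect_class="anticodon_change",
        notation=f"{ref_ac}>{alt_ac}",
        suppressor_trna=suppressor,
    )


def annotate_variant(
    position: int,
    ref_allele: str,
    alt_allele: str,
    features: FeatureTable,
    ref: ReferenceGenome,
) -> EffectAnnotation:
    """Locate a substitution and dispatch to the context-specific rule."""
    context, feature = locate(position, features)
    if context == "CDS":
        return codon_effect(position, ref_allele, alt_allele, feature, ref)
    if context == "tRNA":
        return anticodon_effect(position, ref_allele, alt_allele, feature, ref)
    return EffectAnnotation(
        key=(position, ref_allele, alt_allele),
        context="intergenic",
        effect_class="intergenic",
        notation="-",
    )


def derive_strain_context(
    strain_id: str,
    calls: Iterable[VariantCall],
    features: FeatureTable,
    ref: ReferenceGenome,
) -> StrainContext:
    """Amber-suppressor status from a strain's full call set.

    A strain is an amber suppressor iff any of its calls (parental or
    unique) converts a tRNA anticodon from CGA to CTA.
    """
    amber = False
    for call in calls:
        context, feature = locate(call.position, features)
        if context != "tRNA":
            continue
        eff = anticodon_effect(
            call.position, call.ref_allele, call.alt_allele, feature, ref
        )
        if eff.suppressor_trna:
            amber = True
            break
    return StrainContext(strain_id=strain_id, amber_suppressor=amber)


def apply_readthrough(
    effects: list[EffectAnnotation],
    context: StrainContext,
    features: FeatureTable,
) -> list[EffectAnnotation]:
    """Mark essential-gene amber stop gains as read through in suppressor strains.

    In an amber-suppressor strain a TAG stop gain inside an essential
    gene is survivable because the mutant serine tRNA reads TAG and
    inserts serine; those effects gain ``readthrough_applied`` and the
    ``(S)`` notation suffix. Ochre (TAA) and opal (TGA) stop gains are
    never modified.
    """
    by_name = {f.gene_name: f for f in features}
    out = []
    for eff in effects:
        if (
            context.amber_suppressor
            and eff.effect_class == "stop_gain_amber"
            and eff.context == "CDS"
            and by_name.get(eff.gene_name) is not None
            and by_name[eff.gene_name].essential
            and not eff.readthrough_applied
        ):
            eff = eff.replace(
                readthrough_applied=True, notation=eff.notation + "(S)"
            )
        out.append(eff)
    return out
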