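#!/usr/bin/env python
"""Annotate classified variants with protein-level effects.

Locates each variant against the feature annotation, computes codon
changes and compact protein notation (L36Q, E38E, W286Stop, ...), flags
the tRNA anticodon CGA->CTA amber-suppressor variant, and applies
readthrough annotation: amber stop gains in essential genes of
suppressor strains gain the "(S)" serine-misincorporation suffix.
Writes the parental/unique report tables and a merged VCF to results/.
"""

from pathlib import Path

from supscan import annotate as annotate_mod
from supscan import compare as compare_mod
from supscan import io as io_mod

OUT = Path("scratch/analysis_run")
RESULTS = Path("results")


def main() -> None:
    ref = io_mod.read_fasta(OUT / "reference.fa")
    features = io_mod.read_gff3(OUT / "reference.gff3", ref.length)
    vcf_dir = RESULTS / "vcf"
    call_sets = {
        p.stem: io_mod.read_vcf(p, p.stem) for p in sorted(vcf_dir.glob("strain*.vcf"))
    }
    classified = compare_mod.classify_variants(compare_mod.build_matrix(call_sets))
    contexts = {
        s: annotate_mod.derive_strain_context(s, calls, features, ref)
        for s, calls in call_sets.items()
    }
    n_suppressor = sum(c.amber_suppressor for c in contexts.values())
    print(f"{n_suppressor}/{len(contexts)} strains carry the CGA->CTA "
          f"anticodon variant (amber suppressors)")

    parental_rows, unique_rows, annotation_rows = [], [], []
    for cv in classified:
        pos, ref_b, alt_b = cv.key
        eff = annotate_mod.annotate_variant(pos, ref_b, alt_b, features, ref)
        annotation_rows.append(
            {"position": pos, "ref": ref_b, "alt": alt_b, "context": eff.context,
             "gene": eff.gene_name, "codon_number": eff.codon_number or "-",
             "notation": eff.notation, "effect_class": eff.effect_class,
             "readthrough": eff.readthrough_applied}
        )
        if cv.variant_class == "parental":
            parental_rows.append(
                {"position": pos, "ref": ref_b, "alt": alt_b, "gene": eff.gene_name,
                 "effect": eff.notation if eff.notation != "-" else eff.effect_class,
                 "n_strains": cv.n_strains_present}
            )
        else:
            for strain in cv.carrier_strains:
                (final,) = annotate_mod.apply_readthrough([eff], contexts[strain], features)
                unique_rows.append(
                    {"strain": strain, "position": pos, "ref": ref_b, "alt": alt_b,
                     "gene": final.gene_name,
                     "effect": final.notation if final.notation != "-" else final.effect_class}
                )
                if final.readthrough_applied:
                    print(f"  {strain}: {final.gene_name} {final.notation} — amber stop "
                          f"in an essential gene, survivable via tRNA readthrough")

    parental_rows.sort(key=lambda r: r["position"])
    unique_rows.sort(key=lambda r: (r["strain"], r["position"]))
    io_mod.write_parental_table(parental_rows, RESULTS / "parental_variants.tsv")
    io_mod.write_unique_table(unique_rows, RESULTS / "unique_variants.tsv")
    io_mod.write_annotation_table(annotation_rows, RESULTS / "annotated_variants.tsv")

    class_of = {cv.key: cv.variant_class for cv in classified}
    merged = {}
    for calls in call_sets.values():
        for c in calls:
            merged.setdefault(c.key, c)
    io_mod.write_vcf(list(merged.values()), ref, RESULTS / "merged.vcf", classes=class_of)
    print(f"wrote parental/unique/annotated tables and merged VCF to {RESULTS}")


if __name__ == "__main__":
    main()
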