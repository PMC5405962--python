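"""Readers and writers for the on-disk artifacts.

Every stage of the pipeline communicates through these standard text
formats, so stages are independently runnable and testable: FASTA and
GFF3 for the annotated reference, 4-line FASTQ per strain, optional SAM
for alignments, VCF 4.2 per strain for calls, and TSV for truth sets,
read statistics and classified-variant tables.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    AlignedRead,
    AlignmentStats,
    ClassifiedVariant,
    Feature,
    FeatureTable,
    Read,
    ReferenceGenome,
    TruthVariant,
    VariantCall,
)

# ---------------------------------------------------------------- FASTA


def write_fasta(ref: ReferenceGenome, path: Path) -> None:
    rec = SeqRecord(Seq(ref.sequence), id=ref.id, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: Path) -> ReferenceGenome:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceGenome(id=rec.id, sequence=str(rec.seq).upper())


# ----------------------------------------------------------------- GFF3


def write_gff3(features: FeatureTable, ref_id: str, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {ref_id} 1 {features.genome_length}\n")
        for f in features:
            attrs = [
                f"ID={f.feature_id}",
                f"Name={f.gene_name}",
                f"product={f.product}",
            ]
            if f.kind == "CDS":
                attrs.append(f"essential={'true' if f.essential else 'false'}")
            else:
                attrs.append(f"anticodon_offset={f.anticodon_offset}")
            fh.write(
                "\t".join(
                    [
                        ref_id,
                        "supscan",
                        f.kind,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.kind == "CDS" else ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: Path, genome_length: Optional[int] = None) -> FeatureTable:
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region") and genome_length is None:
                genome_length = int(line.split()[-1])
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";"))
            feats.append(
                Feature(
                    feature_id=attrs["ID"],
                    kind=cols[2],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    gene_name=attrs.get("Name", "-"),
                    product=attrs.get("product", "-"),
                    essential=attrs.get("essential") == "true",
                    anticodon_offset=(
                        int(attrs["anticodon_offset"])
                        if "anticodon_offset" in attrs
                        else None
                    ),
                )
            )
    if genome_length is None:
        genome_length = max(f.end for f in feats)
    return FeatureTable(feats, genome_length)


# ---------------------------------------------------------------- FASTQ


def write_fastq(reads: Iterable[Read], path: Path) -> None:
    # plain 4-line records; constant qualities make this trivial and fast
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: Path) -> list[Read]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            reads.append(Read(read_id=header[1:].strip(), sequence=seq, quality=qual))
    return reads


# ------------------------------------------------------------- truth TSV

_TRUTH_HEADER = ["strain", "position", "ref", "alt", "kind", "class", "effect"]


def write_truth(truth: Sequence[TruthVariant], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TRUTH_HEADER)
        for t in truth:
            w.writerow(
                [
                    t.strain_id,
                    t.position,
                    t.ref_allele,
                    t.alt_allele,
                    t.variant_kind,
                    t.intended_class,
                    t.intended_effect,
                ]
            )


def read_truth(path: Path) -> list[TruthVariant]:
    out = []
    with open(path) as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            kind = row["kind"]
            out.append(
                TruthVariant(
                    strain_id=row["strain"],
                    position=int(row["position"]),
                    ref_allele=row["ref"],
                    alt_allele=row["alt"],
                    variant_kind=kind,
                    intended_class=row["class"],
                    intended_effect=row["effect"],
                    del_length=int(row["alt"]) if kind == "DEL" else 0,
                )
            )
    return out


# ------------------------------------------------------------------ SAM


def write_sam(
    alignments: Sequence[AlignedRead],
    reads: Sequence[Read],
    ref: ReferenceGenome,
    path: Path,
) -> None:
    """Minimal single-reference SAM: FLAG 16 for reverse strand, FLAG 4
    for unmapped (orphans and suppressed reads; the latter additionally
    carry a ZS:Z:suppressed tag). NM holds the mismatch count."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{ref.id}\tLN:{ref.length}\n")
        fh.write("@PG\tID:supscan\tPN:supscan\n")
        for aln, read in zip(alignments, reads):
            if aln.status == "aligned":
                flag = 16 if aln.strand == "-" else 0
                if aln.strand == "-":
                    from .annotate import reverse_complement

                    seq = reverse_complement(read.sequence)
                    qual = read.quality[::-1]
                else:
                    seq, qual = read.sequence, read.quality
                fh.write(
                    f"{aln.read_id}\t{flag}\t{ref.id}\t{aln.position}\t255\t"
                    f"{len(seq)}M\t*\t0\t0\t{seq}\t{qual}\tNM:i:{aln.mismatches}\n"
                )
            else:
                tag = "\tZS:Z:suppressed" if aln.status == "suppressed" else ""
                fh.write(
                    f"{aln.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t"
                    f"{read.sequence}\t{read.quality}{tag}\n"
                )


def read_sam(path: Path) -> tuple[list[AlignedRead], list[Read]]:
    """Read a SAM written by :func:`write_sam` back into parallel triage
    and read lists (reads restored to sequencing orientation)."""
    import pysam

    from .annotate import reverse_complement

    alignments: list[AlignedRead] = []
    reads: list[Read] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for rec in fh:
            seq = rec.query_sequence
            qual = "".join(chr(q + 33) for q in rec.query_qualities) if rec.query_qualities is not None else "I" * len(seq)
            if rec.is_unmapped:
                status = "suppressed" if rec.has_tag("ZS") else "orphan"
                alignments.append(AlignedRead(rec.query_name, status))
                reads.append(Read(rec.query_name, seq, qual))
                continue
            if rec.is_reverse:
                seq = reverse_complement(seq)
                qual = qual[::-1]
            alignments.append(
                AlignedRead(
                    rec.query_name,
                    "aligned",
                    position=rec.reference_start + 1,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=int(rec.get_tag("NM")),
                )
            )
            reads.append(Read(rec.query_name, seq, qual))
    return alignments, reads


# ------------------------------------------------------------------ VCF


def write_vcf(
    calls: Sequence[VariantCall],
    ref: ReferenceGenome,
    path: Path,
    classes: Optional[dict[tuple[int, str, str], str]] = None,
) -> None:
    """VCF 4.2 with DP (depth) and SF (support fraction, 3 decimals);
    a CLASS INFO field is added when a classification map is given."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.id},length={ref.length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Pileup depth">\n')
        fh.write(
            '##INFO=<ID=SF,Number=1,Type=Float,Description="Support fraction">\n'
        )
        if classes is not None:
            fh.write(
                '##INFO=<ID=CLASS,Number=1,Type=String,'
                'Description="Cross-strain class">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: c.position):
            info = f"DP={c.depth};SF={c.support_fraction:.3f}"
            if classes is not None and c.key in classes:
                info += f";CLASS={classes[c.key]}"
            fh.write(
                f"{ref.id}\t{c.position}\t.\t{c.ref_allele}\t{c.alt_allele}"
                f"\t.\tPASS\t{info}\n"
            )


def read_vcf(path: Path, strain_id: str) -> list[VariantCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            info = dict(kv.split("=", 1) for kv in cols[7].split(";") if "=" in kv)
            calls.append(
                VariantCall(
                    strain_id=strain_id,
                    position=int(cols[1]),
                    ref_allele=cols[3],
                    alt_allele=cols[4],
                    support_fraction=float(info["SF"]),
                    depth=int(info["DP"]),
                )
            )
    return calls


# ------------------------------------------------------------ TSV tables


def format_pct(x: float) -> str:
    return f"{x:.2f}%"


def write_stats_table(rows: dict[str, AlignmentStats], path: Path) -> None:
    """Per-strain read-statistics table (totals, triage percentages and
    approximate genome-wide aligned depth)."""
    header = [
        "Strain",
        "Total Reads",
        "Aligned Reads",
        "Aligned %",
        "Suppressed Reads",
        "Suppressed %",
        "Orphan Reads",
        "Orphan %",
        "Approximate Depth",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for strain, s in rows.items():
            w.writerow(
                [
                    strain,
                    s.total_reads,
                    s.aligned_reads,
                    format_pct(s.aligned_pct),
                    s.suppressed_reads,
                    format_pct(s.suppressed_pct),
                    s.orphan_reads,
                    format_pct(s.orphan_pct),
                    f"{s.depth}X",
                ]
            )


def write_parental_table(
    rows: Sequence[dict], path: Path
) -> None:
    """Shared (parental) variants: position ref alt gene effect n_strains."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["position", "ref", "alt", "gene", "effect", "n_strains"])
        for r in rows:
            w.writerow(
                [r["position"], r["ref"], r["alt"], r["gene"], r["effect"], r["n_strains"]]
            )


def write_unique_table(rows: Sequence[dict], path: Path) -> None:
    """Strain-private variants: strain position ref alt gene effect."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["strain", "position", "ref", "alt", "gene", "effect"])
        for r in rows:
            w.writerow(
                [r["strain"], r["position"], r["ref"], r["alt"], r["gene"], r["effect"]]
            )


def write_annotation_table(rows: Sequence[dict], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "position",
                "ref",
                "alt",
                "context",
                "gene",
                "codon_number",
                "notation",
                "effect_class",
                "readthrough",
            ]
        )
        for r in rows:
            w.writerow(
                [
                    r["position"],
                    r["ref"],
                    r["alt"],
                    r["context"],
                    r["gene"],
                    r["codon_number"],
                    r["notation"],
                    r["effect_class"],
                    r["readthrough"],
                ]
            )
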