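"""End-to-end orchestration: simulate -> align -> call -> classify -> annotate.

The *standard scenario* mirrors the structure of the multi-strain
suppressor hunt: a 50-kb toy genome (20 CDS, 1 serine tRNA), 13 strains
all carrying the same 17 parental variants (3 intergenic, 1 synonymous,
2 stop gains, 1 tRNA anticodon CGA->CTA, 10 missense), and one private
variant per strain — 11 SNVs (two of them amber stop gains in essential
genes, two intergenic) and 2 three-base deletions that the SNV-only
caller is blind to. Reads are 36-nt single-end at 150-fold mean coverage
with a 1e-4 uniform substitution error (see docs for why these two are
coupled to the 99% consensus rule).

Every stage writes and re-reads standard text artifacts, so each stage is
independently runnable; config + seed fully determine every output byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import align as align_mod
from . import annotate as annotate_mod
from . import compare as compare_mod
from . import io as io_mod
from . import pileup as pileup_mod
from . import synthdata
from .models import (
    ALL_STRAINS,
    AlignmentStats,
    ReferenceGenome,
    SimulationConfig,
    round_half_up,
)
from .synthdata import UniqueSpec

logger = logging.getLogger(__name__)

#: parental-variant effect mix: 3 intergenic, 1 synonymous, 2 stop gains,
#: 1 tRNA anticodon change, 10 missense = 17 shared variants
STANDARD_SHARED_SPEC = (
    "synonymous",
    "missense",
    "stop_gain",
    "missense",
    "intergenic",
    "missense",
    "intergenic",
    "missense",
    "stop_gain",
    "missense",
    "missense",
    "missense",
    "anticodon",
    "missense",
    "missense",
    "intergenic",
    "missense",
)


def standard_unique_spec(n_strains: int = 13) -> dict[str, UniqueSpec]:
    """Private-variant plan for the standard scenario.

    11 SNV strains (2 intergenic, 2 amber stop gains in essential genes,
    7 missense) and 2 deletion strains; strain ids are strain01..strainNN.
    """
    effects = [
        UniqueSpec("SNV", "intergenic"),
        UniqueSpec("SNV", "stop_gain_amber"),
        UniqueSpec("DEL", del_length=3),
        UniqueSpec("SNV", "intergenic"),
        UniqueSpec("SNV", "missense"),
        UniqueSpec("SNV", "missense"),
        UniqueSpec("SNV", "missense"),
        UniqueSpec("SNV", "missense"),
        UniqueSpec("SNV", "missense"),
        UniqueSpec("SNV", "missense"),
        UniqueSpec("SNV", "stop_gain_amber"),
        UniqueSpec("DEL", del_length=3),
        UniqueSpec("SNV", "missense"),
    ]
    if n_strains != len(effects):
        raise ValueError("standard scenario is defined for 13 strains")
    return {f"strain{i + 1:02d}": spec for i, spec in enumerate(effects)}


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    shared_spec: tuple[str, ...] = STANDARD_SHARED_SPEC
    unique_spec: Optional[dict[str, UniqueSpec]] = None  # default: standard plan
    min_fraction: float = pileup_mod.DEFAULT_MIN_FRACTION
    min_depth: int = pileup_mod.DEFAULT_MIN_DEPTH
    k: int = align_mod.DEFAULT_K
    max_mismatch: int = align_mod.DEFAULT_MAX_MISMATCH
    write_sam: bool = False
    outdir: Path = Path("results/run")

    def resolved_unique_spec(self) -> dict[str, UniqueSpec]:
        if self.unique_spec is not None:
            return self.unique_spec
        if self.sim.n_strains == 13:
            return standard_unique_spec(13)
        # generic fallback: one private missense SNV per strain
        return {
            f"strain{i + 1:02d}": UniqueSpec("SNV", "missense")
            for i in range(self.sim.n_strains)
        }

    def validate(self) -> None:
        self.sim.validate()
        if not 0.5 < self.min_fraction <= 1:
            raise ValueError("min_fraction must lie in (0.5, 1]")


def standard_scenario(seed: int = 0, outdir: Path | str = "results/run") -> PipelineConfig:
    """The frozen study conditions with a caller-visible seed.

    The caller's depth floor scales with coverage (a third of the 150X
    mean): deletion junctions shed short read tails that pile a shifted
    base on the deleted positions at roughly a tenth of genome-wide
    depth, and the floor is what rejects those spurious columns while
    true variant sites sit at full coverage.
    """
    return PipelineConfig(
        sim=SimulationConfig(seed=seed), min_depth=50, outdir=Path(outdir)
    )


@dataclass
class RunReport:
    per_strain_stats: dict[str, AlignmentStats]
    class_counts: dict[str, int]
    per_strain_unique: dict[str, int]
    strains_with_one_unique: int
    strains_with_zero_unique: int
    recovery: dict
    expected_blind_strains: list[str]
    min_support_fraction: Optional[float]
    n_calls_total: int

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["per_strain_stats"] = {
            s: dataclasses.asdict(v) for s, v in self.per_strain_stats.items()
        }
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline, writing all artifacts under config.outdir."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_all = time.perf_counter()

    def stage(name):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    # ---- simulate ------------------------------------------------------
    t = stage("simulate")
    try:
        ref, features = synthdata.generate_reference(config.sim)
        io_mod.write_fasta(ref, out / "reference.fa")
        io_mod.write_gff3(features, ref.id, out / "reference.gff3")
        unique_spec = config.resolved_unique_spec()
        genomes, truth = synthdata.implant_variants(
            ref,
            features,
            config.shared_spec,
            unique_spec,
            seed=config.sim.seed + config.sim.n_strains + 1,
            read_length=config.sim.read_length,
        )
        io_mod.write_truth(truth, out / "truth.tsv")
        for i, (strain, genome) in enumerate(genomes.items(), start=1):
            reads = synthdata.simulate_reads(
                genome, config.sim, seed=config.sim.seed + i, strain_id=strain
            )
            io_mod.write_fastq(reads, out / f"{strain}.fastq")
    except Exception as e:  # noqa: BLE001 - stage-tagged abort
        raise StageError("simulate", e) from e
    logger.info("stage simulate done in %.1fs", time.perf_counter() - t)

    # ---- align + call (per strain, from on-disk artifacts) -------------
    t = stage("align+call")
    try:
        ref = io_mod.read_fasta(out / "reference.fa")
        features = io_mod.read_gff3(out / "reference.gff3", ref.length)
        index = align_mod.build_index(
            ref, config.k, config.sim.read_length, config.max_mismatch
        )
        per_strain_stats: dict[str, AlignmentStats] = {}
        call_sets = {}
        for strain in unique_spec:
            reads = io_mod.read_fastq(out / f"{strain}.fastq")
            alignments, stats = align_mod.align_readset(
                reads, index, ref, config.max_mismatch
            )
            per_strain_stats[strain] = stats
            if config.write_sam:
                io_mod.write_sam(alignments, reads, ref, out / f"{strain}.sam")
            pile = pileup_mod.build_pileup(alignments, reads, ref)
            calls = pileup_mod.call_snvs(
                pile, ref, config.min_fraction, config.min_depth, strain
            )
            call_sets[strain] = calls
            io_mod.write_vcf(calls, ref, out / f"{strain}.vcf")
            logger.info(
                "strain %s: %d/%d reads aligned, %d calls",
                strain, stats.aligned_reads, stats.total_reads, len(calls),
            )
        io_mod.write_stats_table(per_strain_stats, out / "read_stats.tsv")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("align+call", e) from e
    logger.info("stage align+call done in %.1fs", time.perf_counter() - t)

    # ---- classify ------------------------------------------------------
    t = stage("classify")
    try:
        call_sets = {
            strain: io_mod.read_vcf(out / f"{strain}.vcf", strain)
            for strain in unique_spec
        }
        matrix = compare_mod.build_matrix(call_sets)
        classified = compare_mod.classify_variants(matrix)
        truth = io_mod.read_truth(out / "truth.tsv")
        summary = compare_mod.summarize(classified, list(unique_spec), truth)
    except Exception as e:  # noqa: BLE001
        raise StageError("classify", e) from e
    logger.info("stage classify done in %.1fs", time.perf_counter() - t)

    # ---- annotate ------------------------------------------------------
    t = stage("annotate")
    try:
        class_of = {cv.key: cv.variant_class for cv in classified}
        parental_rows, unique_rows, annotation_rows = [], [], []
        contexts = {
            strain: annotate_mod.derive_strain_context(strain, calls, features, ref)
            for strain, calls in call_sets.items()
        }
        for cv in classified:
            pos, ref_b, alt_b = cv.key
            eff = annotate_mod.annotate_variant(pos, ref_b, alt_b, features, ref)
            if cv.variant_class == "parental":
                parental_rows.append(
                    {
                        "position": pos,
                        "ref": ref_b,
                        "alt": alt_b,
                        "gene": eff.gene_name,
                        "effect": eff.notation if eff.notation != "-" else eff.effect_class,
                        "n_strains": cv.n_strains_present,
                    }
                )
            else:
                for strain in cv.carrier_strains:
                    (final,) = annotate_mod.apply_readthrough(
                        [eff], contexts[strain], features
                    )
                    unique_rows.append(
                        {
                            "strain": strain,
                            "position": pos,
                            "ref": ref_b,
                            "alt": alt_b,
                            "gene": final.gene_name,
                            "effect": final.notation
                            if final.notation != "-"
                            else final.effect_class,
                        }
                    )
            annotation_rows.append(
                {
                    "position": pos,
                    "ref": ref_b,
                    "alt": alt_b,
                    "context": eff.context,
                    "gene": eff.gene_name,
                    "codon_number": eff.codon_number if eff.codon_number else "-",
                    "notation": eff.notation,
                    "effect_class": eff.effect_class,
                    "readthrough": eff.readthrough_applied,
                }
            )
        parental_rows.sort(key=lambda r: r["position"])
        unique_rows.sort(key=lambda r: (r["strain"], r["position"]))
        io_mod.write_parental_table(parental_rows, out / "parental_variants.tsv")
        io_mod.write_unique_table(unique_rows, out / "unique_variants.tsv")
        io_mod.write_annotation_table(annotation_rows, out / "annotated_variants.tsv")
        # merged multi-strain VCF with CLASS tags
        merged = {}
        for calls in call_sets.values():
            for c in calls:
                merged.setdefault(c.key, c)
        io_mod.write_vcf(list(merged.values()), ref, out / "merged.vcf", classes=class_of)
    except Exception as e:  # noqa: BLE001
        raise StageError("annotate", e) from e
    logger.info("stage annotate done in %.1fs", time.perf_counter() - t)

    all_fracs = [
        c.support_fraction for calls in call_sets.values() for c in calls
    ]
    report = RunReport(
        per_strain_stats=per_strain_stats,
        class_counts=summary["class_counts"],
        per_strain_unique=summary["per_strain_unique"],
        strains_with_one_unique=summary["strains_with_one_unique"],
        strains_with_zero_unique=summary["strains_with_zero_unique"],
        recovery=summary.get("recovery", {}),
        expected_blind_strains=summary.get("expected_blind_strains", []),
        min_support_fraction=min(all_fracs) if all_fracs else None,
        n_calls_total=len(all_fracs),
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline done in %.1fs", time.perf_counter() - t_all)
    return report


def stats_table_rows(report: RunReport) -> list[list[str]]:
    """Rendered read-statistics rows (counts, 2-decimal percentages with
    trailing %, integer depth with trailing X)."""
    rows = []
    for strain, s in report.per_strain_stats.items():
        rows.append(
            [
                strain,
                str(s.total_reads),
                str(s.aligned_reads),
                io_mod.format_pct(s.aligned_pct),
                str(s.suppressed_reads),
                io_mod.format_pct(s.suppressed_pct),
                str(s.orphan_reads),
                io_mod.format_pct(s.orphan_pct),
                f"{s.depth}X",
            ]
        )
    return rows


def render_stats_row(
    total: int, aligned: int, suppressed: int, orphan: int
) -> tuple[str, str, str]:
    """Percent triple for one statistics row, as printed in reports."""
    stats = AlignmentStats.from_counts(total, aligned, suppressed, orphan, 36, 1)
    return (
        io_mod.format_pct(stats.aligned_pct),
        io_mod.format_pct(stats.suppressed_pct),
        io_mod.format_pct(stats.orphan_pct),
    )
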