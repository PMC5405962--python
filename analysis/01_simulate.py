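#!/usr/bin/env python
"""Simulate the 13-strain resequencing experiment.

Generates the 50-kb annotated toy reference, implants the 17 shared
(parental) variants and one private variant per strain (11 SNVs, 2
three-base deletions), and writes 36-nt single-end reads at 150X per
strain. Bulky artifacts (FASTQ) land in scratch/; the small truth and
annotation files are copied into results/.
"""

import shutil
from collections import Counter
from pathlib import Path

from supscan import io as io_mod
from supscan.pipeline import standard_scenario
from supscan import synthdata

OUT = Path("scratch/analysis_run")
RESULTS = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cfg = standard_scenario(seed=0, outdir=OUT)

    ref, features = synthdata.generate_reference(cfg.sim)
    io_mod.write_fasta(ref, OUT / "reference.fa")
    io_mod.write_gff3(features, ref.id, OUT / "reference.gff3")

    unique = cfg.resolved_unique_spec()
    genomes, truth = synthdata.implant_variants(
        ref, features, cfg.shared_spec, unique,
        seed=cfg.sim.seed + cfg.sim.n_strains + 1,
        read_length=cfg.sim.read_length,
    )
    io_mod.write_truth(truth, OUT / "truth.tsv")
    for i, (strain, genome) in enumerate(genomes.items(), start=1):
        reads = synthdata.simulate_reads(genome, cfg.sim, cfg.sim.seed + i, strain)
        io_mod.write_fastq(reads, OUT / f"{strain}.fastq")

    shutil.copy(OUT / "truth.tsv", RESULTS / "truth.tsv")
    shutil.copy(OUT / "reference.gff3", RESULTS / "reference.gff3")

    effects = Counter(t.intended_effect for t in truth)
    n_shared = sum(t.strain_id == "ALL" for t in truth)
    n_del = sum(t.variant_kind == "DEL" for t in truth)
    print(f"reference: {ref.length} bp, {len(features.cds)} CDS, "
          f"{len(features.trnas)} tRNA")
    print(f"implanted {len(truth)} variants: {n_shared} shared, "
          f"{len(truth) - n_shared} private ({n_del} deletions)")
    print(f"effect mix: {dict(effects)}")
    print(f"simulated {len(genomes)} strains x "
          f"{synthdata.n_reads_for(cfg.sim, ref.length)} reads -> {OUT}")


if __name__ == "__main__":
    main()
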