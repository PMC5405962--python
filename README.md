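# supscan

Hunting suppressor mutations in multi-strain bacterial resequencing data.

## The problem

When a bacterium survives an otherwise lethal genetic insult — say, its
cell-division GTPase FtsZ replaced by a barely-functional foreign or
mutant variant — the survivor usually carries a *suppressor mutation*
somewhere else in its genome. Finding that mutation by whole-genome
resequencing of many independent suppressor strains rests on a simple
comparative argument: variants relative to the public reference that
appear in **every** strain are divergences of the common lab parent
(*parental* mutations), while a variant found in **exactly one** strain
is that strain's suppressor candidate (*unique* mutation).

`supscan` implements that hunt end to end as a tested, reusable pipeline
over synthetic data, so every stage is verifiable against ground truth:

1. **simulate** — a toy annotated reference (CDS + tRNA genes), clonal
   strain genomes sharing an implanted parental variant set plus one
   private variant each (SNV or small deletion), and 36-nt single-end
   reads with uniform substitution errors;
2. **align** — seed-and-extend placement using three disjoint 12-mers
   per read orientation (pigeonhole: a read with ≤ 2 mismatches always
   has one exact seed), full-length Hamming extension, mismatch budget
   2; reads mapping equally well to more than one locus are
   *suppressed*, reads with no placement are *orphans*;
3. **call** — per-position pileup; a SNV is called where ≥ 99% of
   covering reads agree on a non-reference base (with a depth floor);
4. **classify** — the variant-by-strain presence matrix partitions keys
   into parental / unique / shared-subset;
5. **annotate** — codon effects in compact notation (`L36Q`, `E38E`,
   `W286Stop`), tRNA anticodon logic (CGA→CTA turns a Ser-tRNA into an
   **amber suppressor** that reads the TAG stop codon), and readthrough
   annotation: an amber stop gain in an essential gene is survivable in
   a suppressor strain and is written e.g. `Q11Amber(S)` for the serine
   misincorporation.

The caller is deliberately SNV-only: strains whose private lesion is a
deletion yield *no* unique call, reproducing the characteristic
blindness of this kind of pipeline to indels and rearrangements.

## Worked example

The standard scenario: 50-kb genome, 20 CDS + 1 tRNA, 13 strains, 17
shared variants, 11 private SNVs and 2 private 3-bp deletions, 36-nt
reads at 150X with a 1e-4 substitution error rate.

```sh
python analysis/01_simulate.py
python analysis/02_align_reads.py
python analysis/03_call_variants.py
python analysis/04_classify_variants.py
python analysis/05_annotate_effects.py
```

The classification step prints:

```
28 distinct variant keys across 13 strains
parental (all strains): 17
unique (one strain):    11
shared_subset (flagged): 0
strains with exactly one unique SNV: 11
strains with zero unique SNVs:       2 (deletion carriers: ['strain03', 'strain12'])
recovery vs truth: {'parental': {'sensitivity': 1.0, 'precision': 1.0}, 'unique': {'sensitivity': 1.0, 'precision': 1.0}}
```

All 17 implanted parental variants are recovered in all 13 strains, the
11 SNV strains each show exactly their one implanted suppressor
candidate, and the 2 deletion strains show none — the caller cannot see
them. The annotation step then reports, for example:

```
13/13 strains carry the CGA->CTA anticodon variant (amber suppressors)
  strain02: gene20 K286Amber(S) — amber stop in an essential gene, survivable via tRNA readthrough
```

and the call step confirms the consensus criterion:

```
minimum support fraction over all calls: 0.9932
```

Small outputs (read statistics, per-strain VCFs, parental/unique tables,
merged VCF) land under `results/`; bulky intermediates (FASTQ, SAM)
under `scratch/`. The same pipeline is available as a CLI
(`supscan run|simulate|align|call|classify|annotate|report`, with
`--config/--seed/--outdir`) and as a library (`supscan.pipeline.run`).

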