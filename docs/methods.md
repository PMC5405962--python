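# Methods

## Model and procedure

`supscan` treats suppressor hunting as a pure comparative-genomics
computation over clonal haploid isolates. Each of *n* strains derives
from one lab parent; relative to the public reference every strain
carries (i) the parent's divergences — the *parental* set, identical in
all strains — and (ii) at most one strain-*private* lesion, the
suppressor candidate. The pipeline recovers this partition from reads
alone: align, call per-strain consensus SNVs, intersect across strains.

Classification is exact set logic on call keys `(position, ref, alt)`:
present in all strains → parental; in exactly one → unique; anything in
between → `shared_subset`, which the clonal single-suppressor model says
should not occur and which is therefore flagged loudly rather than
dropped. Matching is exact; no near-position merging is attempted in
this SNV-only world.

## Alignment rule

Reads are accepted with at most 2 Hamming mismatches over their full
36 nt. The published description of this class of pipeline speaks of
"consecutive mismatched nucleotides"; read literally, a consecutive-only
rule would accept arbitrarily many scattered mismatches and defeat the
stated purpose of skipping quality screening, so the budget is applied
to total mismatches (the classic `-v 2` alignment policy). Candidate
loci come from exact lookup of the read's three disjoint 12-mers on both
orientations; by pigeonhole, any placement within the 2-mismatch budget
matches at least one seed exactly, so seeding loses nothing. Suppression
is decided among best-tier placements only: a unique 0-mismatch hit with
extra 2-mismatch hits is aligned, not suppressed. Reported positions are
always the leftmost forward-reference coordinate, with strand kept
separately. Percentages in the statistics table are rounded half-up to
two decimals; approximate depth is `aligned_reads × read_length /
genome_length`, rounded to the nearest integer — the alternative
"average over mapped positions" definition gives slightly different
numbers and is not used.

## Consensus calling and the error/depth/threshold triangle

A site is called iff depth ≥ `min_depth` and the most frequent base
differs from the reference with support `count/depth ≥ min_fraction`
(default 0.99). Ties break lexicographically and are logged; above 50%
support a tie cannot produce a call. Consensus equal to the reference is
never reported.

The three numbers — per-base error rate *e*, site depth *D*, and the
hard 99% cutoff — are not independent. Support at a true SNV site is
`(D−k)/D` with `k ~ Binomial(D, e)` erroneous reads, so a call survives
only while `k ≤ 0.01·D`. Two regimes fail: at desk-scale depth
(*D* ≈ 30) a *single* erroneous read drops support to 96.7%, so the miss
probability per site is `1−(1−e)^D` (≈ 9% at e = 0.003); and even at
*D* ≈ 150, e = 0.003 leaves ≈ 7% of sites with ≥ 2 errors below the
cutoff. A pipeline that reports *every* true site at ≥ 99% agreement —
the empirical signature of this study design, where most sites show
100% — therefore requires `D·e ≪ 1`. The standard scenario consequently
pairs 150X coverage (inside the 107–254X range typical of the original
study design) with e = 1e-4, giving an expected 0.02 misses over all
17×13 parental site-strain checks. These are frozen study conditions,
not tuning knobs: they were fixed by this analysis before the pipeline
existed and are not revisited.

### Depth floor and deletion-junction phantoms

`min_depth` exists to reject spurious calls in low-coverage columns, and
its useful value scales with coverage. The sharpest spurious class is
the *deletion-junction phantom*: reads whose last 1–3 bases cross a
deletion junction still fit the 2-mismatch budget and all deposit the
same shifted base onto the deleted reference positions — a unanimous,
100%-support column at roughly a tenth of genome-wide depth (≈ 12 reads
at 150X). A visual review would discard such a ragged, one-sided,
low-coverage column instantly; the automated equivalent is the depth
floor, set in the standard scenario to a third of mean coverage (50 at
150X). True sites sit at full coverage (P(depth < 50) ≈ 1e-20 at 150X),
so the floor costs nothing. The function-level default remains 10 for
small hand-built pileups.

## Synthetic data: what it emulates, what it does not

The generator produces a single linear reference (a stand-in for a
circular chromosome; no reads wrap the origin), `gene_count` CDS and
`trna_count` tRNA features, non-overlapping with ≥ 60-bp gaps. Every CDS
begins ATG, ends TAA/TGA on its coding strand (TAG is avoided as a
natural stop so amber readthrough stays a variant-level phenomenon), and
contains no internal in-frame stop. Exactly one tRNA carries the CGA
anticodon — the serine-tRNA analogue whose CGA→CTA mutation creates an
amber suppressor; tRNAs are stored on the forward strand so the
anticodon reads directly. Essentiality is an annotation attribute
assigned at generation (≈ 40% of genes, forced to include at least two
essential and two non-essential), not a biological lookup.

Variant implanting is effect-driven: each request (intergenic,
synonymous, missense, stop_gain, stop_gain_amber, anticodon, or a
deletion) is realised by searching the genome for a substitution whose
annotated consequence matches, then re-verified through the annotation
module — simulator and annotator are mutually consistent by
construction. `stop_gain_amber` requests target essential genes and
plain `stop_gain` non-essential ones, mirroring the biology that an
unsuppressed premature stop is only tolerable outside essential genes.
Implanted positions are pairwise ≥ one read length apart (so no read
spans two variants) and ≥ 50 bp from the genome ends (full coverage).
Private deletions default to 3 bp: any length is equally invisible to an
SNV caller, and 3 avoids frameshift bookkeeping in the truth
annotation. One strain in the standard scenario stands in for an
observed adjacent di-nucleotide substitution with a single SNV — the
classifier treats adjacent SNVs as separate keys, so one key per strain
keeps "exactly one unique call" well-defined.

Reads are uniform single-end 36-mers, either strand with probability
1/2, each base substituted independently with probability `error_rate`
to a uniformly chosen different base; qualities are constant (the
aligner ignores them, as does the acceptance rule it implements). Read
count is `round(mean_depth × L / read_length)`. Not emulated: paired
ends, quality-dependent or end-of-read error enrichment, PCR
duplicates, coverage bias, insertion elements (real multi-mapping comes
almost entirely from repeats, which a random toy genome lacks — so
suppressed fractions here are ≈ 0%, unlike the 3–5% seen with real
genomes), and structural variation beyond small deletions. Passing
tests therefore demonstrate the *logic* of the pipeline — triage
accounting, consensus arithmetic, partition, annotation — not its
robustness to real-platform artefacts.

## Standard scenario (frozen)

50-kb genome, 20 CDS + 1 tRNA; 13 strains; 17 shared variants
(3 intergenic, 1 synonymous, 2 stop gains in non-essential genes,
1 anticodon CGA→CTA, 10 missense); private variants: 2 intergenic SNVs,
2 amber stop gains in essential genes, 7 missense SNVs, 2 three-bp
deletions; 36-nt reads, 150X, e = 1e-4; aligner k = 12, budget 2;
caller 0.99 / depth floor 50; seed 0 by default, with per-strain read
streams at `seed + strain_index` and implanting at `seed + n_strains + 1`.
The full run (≈ 2.7 M reads) takes ~2 minutes on one CPU; tests use a
reduced 10-kb / 3-strain configuration where the full scenario is not
the point.

## Numerical and degenerate-input choices

Percentages: decimal round-half-up, 2 digits; empty read sets report
0.00 with a log warning. Read counts and depth round half away from
zero. Non-ACGT reads orphan (counted, logged) rather than raise.
Overlapping features are rejected at table construction. Two strains
disagreeing on a reference allele at one position raise a consistency
error — with a shared reference that can only be an upstream bug. Amber
notation: stop gains are written `<ref><codon>Stop` except TAG gains in
*essential* genes, written `<ref><codon>Amber`, gaining the `(S)` suffix
only when the strain's own call set (parental + unique) contains the
CGA→CTA anticodon variant; ochre/opal are never readthrough-annotated.

## Known limitations

Exhaustive-dictionary seeding holds the whole k-mer table in a Python
dict — fine at toy scale, unsuitable for megabase genomes. The caller
has no gapped logic, genotype likelihoods or quality weighting by
design. The deletion-junction phantom is filtered by depth, not by a
positional-bias model; a deletion sitting in a region whose 3-shifted
sequence happens to match the reference could in principle evade both
the orphan filter and the depth floor, though not at a unanimous-support
level. Strain genomes are fully clonal: no within-strain heterogeneity.
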