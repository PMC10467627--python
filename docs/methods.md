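# Methods

`cgpval` implements the statistical machinery behind the analytic
validation of a tumor-normal whole-exome / whole-transcriptome profiling
assay: a synthetic cohort generator that realizes the study conditions,
the callers that operate on its count-level evidence (somatic small
variants, MSI, TMB, CNA, fusions), and the validation statistics that
summarize agreement with a reference method.  This note records the
models, the parameters that matter, and the design choices made where
the procedure was genuinely open.

## Generative model for matched tumor/normal samples

The simulator works at the level of read counts, not reads.  Alignment,
base-quality modelling, and FFPE chemistry are out of scope; what is
preserved is the statistical structure that the downstream analysis
actually consumes.

**Small variants.**  A somatic variant with cancer-cell fraction `ccf`
in a tumor of purity `p`, heterozygous on a diploid background, has
expected allele frequency

    AF = p * ccf / 2

Tumor alternate reads are Binomial(depth, AF); the matched normal's
alternate reads are Binomial(depth, 1e-3), a flat per-site
sequencing-error rate chosen so the normal-evidence rejection rule has
realistic nonzero input.  Germline heterozygotes sit at AF 0.5 (and
homozygotes at 1.0) in *both* samples, independent of purity.  A small
number of artifact sites (default 10/sample) carry tumor AFs of
0.5–3% and no normal signal.  Tumor depth is Poisson around a median
of 500x, with a configurable fraction of targets (default 10%)
"boosted" to 1500x, and the normal at 150x — the assay's stated
coverage design.  Tumor content below 20% raises a QC-gate error
unless explicitly overridden, mirroring the inclusion rule.

**Variant counts.**  When not given explicitly, the number of
(nonsynonymous) somatic variants is Poisson(tmb_target x footprint_mb)
— so a 10 mut/Mb target over the default 35 Mb footprint yields ~350
variants — split 82/18 into SNVs and indels (the ratio of the
validation's event counts).  The germline count defaults to a third of
the somatic count, so that roughly a quarter of the candidate calls a
tumor-only caller sees are germline, matching the germline:somatic mix
the validation reported for its reference method.  All simulated small
variants carry the nonsynonymous flag by default; consequence
annotation is out of scope, and the flag is what TMB consumes.
Population allele frequencies for germline variants are drawn common
(U(0.01, 0.5), 90%) or rare (U(0, 0.001), 10%); rare germline is what
leaks through a tumor-only database filter.

**Footprint.**  The TMB footprint is "exome-wide" in the assay without
a printed size; 35 Mb is the conventional size of the captured exome
and is configurable.

**Microsatellites.**  Each of the 117 homopolymer loci has a germline
repeat length (8–20 units).  Reads scatter around it with a geometric
stutter kernel, P(offset k) proportional to 0.15^|k| for |k| <= 3.  An
unstable locus in an MSI-H tumor mixes in a second length population
shifted by +-2–3 units with a wider kernel (decay 0.35) at weight
equal to tumor purity; stable loci draw tumor and normal from the same
kernel.  An MSI-H sample has round(unstable_fraction x n_loci) truly
unstable loci (default 20% -> 23 of 117); an MSS sample has none.

**CNA and fusion evidence.**  Gene-level coverage ratios follow the
purity mixture `ratio = (p*CN + (1-p)*2)/2` with log-normal
multiplicative noise (sigma 0.05); fusion supporting reads are Poisson
around the configured mean.

**Seeding.**  One master seed; per-sample streams are spawned with
numpy `SeedSequence`, so any subset of a cohort reproduces exactly and
identical (config, seed) is bitwise-identical output.

## Somatic classification

A candidate is **somatic** when its tumor AF strictly exceeds the 5%
reportable threshold, carries at least 4 alternate reads, and the
matched normal shows no significant evidence for the allele.
"Significant evidence" is: at least 3 alternate reads in the normal
AND (one-sided exact binomial p < 0.01 against the 1e-3 error rate, OR
normal AF > 2%).  The 3-read floor applies to both branches
deliberately: at 150x normal coverage, two stray error reads already
drive the binomial p below 0.01, and a rule without the floor vetoes
~1% of true somatic variants — incompatible with the >=99% recovery
this design targets.  Production tumor-normal callers gate their
normal-evidence filters on a minimum alternate-read count for the same
reason.  Variants with normal evidence are labelled **germline** when
the normal AF is diploid-consistent (0.3–0.7 or >=0.9), otherwise
rejected.  All thresholds live in `ClassificationThresholds`.

Tumor-only mode never consults the normal: it keeps any candidate
above the AF/read floors whose population AF is below 1%.  Rare
germline variants therefore pass — by construction, since the mode
exists to demonstrate the contrast (inflated false somatic calls and
TMB) against tumor-normal subtraction.

The truth-set builder applies the validation study's two inclusion
criteria to reference-method records: reported AF strictly >5%, and
not rejected as germline by the tumor-normal analysis.

## MSI calling

Each evaluable locus (>=30 reads in both histograms) is tested for
tumor-vs-normal homogeneity of the repeat-length distribution.  The
main path is a chi-squared test on length bins merged (order-
preserving) until every expected count reaches 5 — with a 500x/150x
depth imbalance the binding constraint is the shallower row, so the
merge target scales by `total/min(row sums)`.  When the guard cannot
be met, an exact Monte-Carlo permutation test (2,000 draws of the
tumor row from the multivariate hypergeometric fixed-margins null)
takes over; its RNG seed derives from the table contents, keeping the
p-value a deterministic function of the histograms.  A locus is
unstable at p < 0.01.

A sample is **MSI-H** when strictly more than 10% of evaluable loci
are unstable, else **MSS**.  The denominator is evaluable loci rather
than the fixed 117; at nominal coverage the two coincide, and the
evaluable-only denominator avoids penalizing low-coverage samples.
Zero evaluable loci is an explicit error, never a status.

## TMB

TMB = nonsynonymous somatic calls / footprint.  Indels count toward
TMB (configurable).  The >=10 mut/Mb high/low split exists only to
stratify precision summaries; the number itself is the result.

## CNA

The copy-number estimate inverts the purity mixture:
`CN = (ratio*2 - (1-p)*2)/p`, clamped at zero.  Amplifications are
called at CN >= 8, the assay's predefined cutoff; whole-gene deletions
at CN <= 0.5, homozygous-loss territory (the assay validates deletions
by PCR without printing a numeric rule, so the cutoff is this
package's choice).  Both the raw ratio and the purity-corrected
estimate are available.

## Fusions

A fusion is reportable when either partner is in the 284-gene
footprint (shipped as `data/fusion_genes.txt`, symbols upper-cased at
comparison).  The list intentionally includes tumor suppressors (APC,
NF2, ...) whose truncating fusions inactivate them.  Presence is a
threshold on supporting reads, default 5 — split-read detection is the
job of an RNA aligner and out of scope here.

## Validation statistics

With no true-negative universe in the design, the summary statistics
are PPA = TP/(TP+FN), PPV = TP/(TP+FP), and overall accuracy for
binary status calls, each with a Clopper-Pearson (exact beta-quantile)
95% CI; Wilson is available as an option.  Replicate precision is the
mean pairwise **Jaccard** agreement over positive call sets — "percent
agreement" needs a denominator and the symmetric intersection-over-
union is the choice least favorable to either replicate.  The
replicate CV is sample SD / mean.  AF reproducibility fits a
through-origin least-squares line (slope = Σxy/Σx², with the
uncentered r²), matching the zero-intercept form in which such
comparisons are reported.  Percentages are rounded half-up to one
decimal, the convention the printed tables follow.

## Limit of detection

Dilutions of 80/50/30/20/10/5/2.5% tumor into matched normal, at 200
ng and 150 ng DNA inputs, mapped linearly to depth (200 ng -> the
undiluted depth, so 150 ng -> 0.75x).  The truth set is the somatic
variants detected undiluted; each truth variant's expected AF in a
dilution is its measured undiluted AF times the fraction.  Detection
requires >= 4 alternate reads under binomial resampling, times a
Bernoulli draw from a logistic sensitivity curve in expected AF with
midpoint 4% and scale 0.004.  The midpoint sits where real callers'
sensitivity rolls off; the scale is set so the curve is effectively
saturated above ~6% AF and effectively off below ~2.5%.  Per-bin PPA
over the default expected-AF grid (0–2.5–5–10–20–50–100%) then yields
the LOD: the lowest bin at >= 95% PPA with all higher bins also
passing.  Under these settings the LOD interval is 5–10% AF at both
DNA inputs, with per-bin PPA differing by well under 5 points between
them.

## QC gates

All printed ranges are inclusive: tumor content >= 20%, DNA input
150–750 ng, A260/230 1.7–2.9, Q30 >= 75%, and — when RNA is present —
RNA input 50–200 ng, DV200 >= 30%, and > 200 M RNA reads.  The verdict
is pure and enumerates every violated gate.  The library fragment
range (195–350 bp) is enforced only when measured; PhiX outside
~0.2–1% warns without failing, since the printed row reads as a
description rather than a gate.

## Problem sizes and runtime

The test suite and the acceptance script size their simulations to
what the statistics need rather than to the validation study's full
cohort: classification recovery uses one 2,600-variant sample, TMB
recovery 50 replicates per target (targets 3/10/50 mut/Mb), the
tumor-only contrast 200 paired samples, MSI precision 10 samples x 10
replicates at 117 loci, and the LOD series 600 somatic variants across
7 dilutions x 2 inputs.  The full suite runs in well under a minute on
one CPU.

## What passing tests do and do not show

The generator realizes the statistical assumptions the analysis makes
— binomial allele sampling, independent loci, flat error, clean truth
labels.  Passing recovery tests therefore demonstrates the *internal
consistency* of the callers with the stated model, and the concordance
arithmetic demonstrates the statistics are computed as defined.  They
do not demonstrate performance on real FFPE specimens: deamination
artifacts, mapping error, purity estimation error, subclonal structure
and stromal heterogeneity are all absent from the model, and the
printed clinical concordance values (99.4% SNV PPA etc.) are
properties of the original clinical comparison, reproduced here only
as arithmetic on the published counts.

## Known limitations

- The 117-locus MSI panel composition is not public; loci are
  synthetic homopolymers, and tumor-only MSI is unsupported.
- Copy-number evidence is gene-level by construction; no segmentation,
  no allele-specific CN.
- The logistic detection term in the LOD model is a stand-in for a
  caller's sensitivity curve, with declared parameters rather than
  fitted ones.
- Tumor-only TMB inflation depends on the configured rare-germline
  density; the slope it produces is qualitative (direction and bound),
  not an estimate of any particular cohort's value.
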