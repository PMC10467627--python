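# cgpval

Analytic-validation machinery for a tumor-normal comprehensive genomic
profiling (CGP) assay, as a reusable, tested Python package.

Clinical CGP assays call somatic SNVs/indels, copy-number alterations
(CNAs), gene fusions, microsatellite instability (MSI) and tumor
mutational burden (TMB) from matched tumor/normal sequencing, and are
validated against an orthogonal reference method with positive percent
agreement (PPA), positive predictive value (PPV), replicate precision,
and a limit-of-detection (LOD) dilution study.  The clinical specimens
behind such validations are never public.  `cgpval` makes the entire
analysis layer testable anyway: a synthetic cohort simulator generates
matched tumor/normal evidence with full ground truth, and every
downstream component — germline subtraction, the MSI decision rule, TMB
in tumor-normal vs tumor-only mode, CNA purity correction, fusion
reportability, and all validation statistics — runs end to end on it.

It is aimed at people building or evaluating somatic calling pipelines
and validation harnesses who need a ground-truthed sandbox with the
statistical structure of a real assay.

## The model in brief

- A somatic variant at cancer-cell fraction *c* in a tumor of purity
  *p* (diploid, heterozygous) has expected allele frequency
  **AF = p·c/2**; alternate reads are Binomial(depth, AF) at 500×
  tumor / 150× normal coverage. Germline heterozygotes sit at AF 0.5
  in both samples.
- A candidate is **somatic** iff AF > 5% (with ≥4 alt reads) and the
  matched normal shows no significant evidence (exact binomial test
  against the 10⁻³ error rate, with a 3-read floor).
- **MSI-H** iff >10% of 117 homopolymer loci have tumor repeat-length
  distributions significantly diverged from the normal (chi-squared on
  merged bins, permutation fallback).
- **TMB** = nonsynonymous somatic count / 35 Mb; tumor-only mode leaks
  rare germline variants and is never below the tumor-normal value.
- **CNA**: CN = (2·ratio − 2(1−p))/p, amplification iff CN ≥ 8.
- **PPA** = TP/(TP+FN), **PPV** = TP/(TP+FP), with exact
  Clopper-Pearson intervals; no true-negative universe exists in this
  design.
- **LOD**: dilutions at 80–2.5% tumor fraction; the LOD is the lowest
  expected-AF bin with PPA ≥ 95%.

See `docs/methods.md` for the full account.

## Worked example

```python
from cgpval import (SimulationConfig, simulate_sample_pair, classify_sample,
                    classify_tumor_only, call_msi, compute_tmb)

cfg = SimulationConfig(tmb_target=10, msi_status="MSI-H",
                       unstable_locus_fraction=0.25, seed=11)
pair = simulate_sample_pair(cfg, seed=11)

calls = classify_sample(pair.variants)          # tumor-normal mode
print(compute_tmb(calls).tmb)                   # 10.77
print(compute_tmb(classify_tumor_only(pair.variants)).tmb)  # 11.14
msi = call_msi(pair.loci)
print(msi.status, msi.n_unstable, msi.n_evaluable)  # MSI-H 30 117
```

The sample carries 513 candidate variants; tumor-normal classification
recovers 377 somatic (TMB 377/35 = 10.77 mut/Mb, near the 10 mut/Mb
target), labels 126 germline, and rejects 10 low-AF artifacts.
Tumor-only mode cannot remove the rare germline variants the population
database misses, so its TMB is higher (11.14) — the inflation that
matched-normal subtraction exists to prevent.  30 of 117 microsatellite
loci test unstable (25.6% > 10%), so the sample is MSI-H.

Concordance statistics work directly on 2×2 counts:

```python
from cgpval import ConcordanceTable, ppa, ppv, binomial_ci, percent
t = ConcordanceTable(tp=2957, fp=10, fn=19)
percent(ppa(t)), percent(ppv(t))     # (99.4, 99.7)
[percent(x) for x in binomial_ci(2957, 2976)]  # [99.0, 99.6]
```

A CLI mirrors the library: `cgpval simulate | qc | call | msi | tmb |
cna | fusion | validate | lod | report` (see `--help` on each).

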