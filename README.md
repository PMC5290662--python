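# mitocohort

Cohort-scale analysis of mitochondrial DNA variation and abundance from
sequencing pileups: heteroplasmy quantification, haplogroup-aware
rare-variant classification, gene/complex case-control burden testing, and
relative mtDNA copy-number estimation — with a synthetic-cohort generator
that provides full ground truth for validation.

The package is aimed at studies that sequence the mitochondrial genome
across large case-control cohorts (for example post-mortem brain collections
spanning Alzheimer's disease, CJD, Parkinson's/Lewy-body disease, FTD-ALS
and controls) and ask three questions: do rare inherited mtDNA variants
associate with disease, does somatic heteroplasmy accumulate with age or
disease, and does mtDNA abundance differ between groups?

## The model in brief

* **Heteroplasmic fraction.** At each site the variant allele's fraction is
  HF = 100·v/d (site depth for SNVs/deletions, 5′-flank reads for
  insertions). Sites pass with mean base quality ≥ 25 and depth ≥ 5.
  HF < 10% is treated as homoplasmic reference (dropped), HF > 90% as
  homoplasmic alternate, and 10% ≤ HF ≤ 90% as heteroplasmic.
* **Haplogroups and rarity.** Haplogroups are assigned by marker overlap,
  score = ½(|S∩M|/|M| + |S∩M|/|S|) over the sample's homoplasmic variants S
  and marker set M. Within a haplogroup, MpAF is the fraction of
  reference-panel individuals carrying an allele; rare means MpAF < 0.05,
  novel means absent from panel and catalogs.
* **Burden tests.** A sample carries a gene (or OXPHOS complex) when it has
  ≥ 1 qualifying variant there; carrier 2×2 tables are tested with the
  two-sided Fisher exact test (point-probability rule), Bonferroni-corrected
  over the 37 mtDNA genes (0.05/37 ≈ 0.0014). Variant counts versus age use
  a Poisson log-linear model count ~ Poisson(exp(β₀ + β₁·age)).
* **Copy number.** Relative mtDNA content is the mean mtDNA read depth over
  all 16,569 positions divided by the mean nuclear exome depth, compared
  between groups by Mann-Whitney and against age by Spearman rank
  correlation.

See `docs/methods.md` for assumptions, parameter defaults, and the
simulator's scope.

## Worked example

```python
from mitocohort import (fisher_two_sided, bonferroni_threshold, proportion_pct,
                        SimulationConfig, GroupSpec, generate_cohort,
                        generate_pileup, call_sample, synthetic_model,
                        heteroplasmy_summary)

# A rare-variant carrier table: 30/282 case carriers vs 16/344 controls
p = fisher_two_sided([[30, 252], [16, 328]])
print(f"carrier rate {proportion_pct(30, 282)}%, Fisher p = {p:.3g}, "
      f"corrected threshold {bonferroni_threshold(0.05, 37):.2g}")

# Simulate a small cohort and run the caller over its pileups
cfg = SimulationConfig(
    groups={"AD": GroupSpec(n=30, age_mean=78.1, age_sd=11.6),
            "Control": GroupSpec(n=40, age_mean=78.1, age_sd=12.0)},
    seed=1)
model = synthetic_model()
samples, truths = generate_cohort(cfg, reference=model.reference)
calls = []
for t in truths:
    calls += call_sample(generate_pileup(t, cfg, model.reference),
                         model, t.sample_id)
s = heteroplasmy_summary(calls, samples)
print(f"{s['n_het_calls']} heteroplasmic calls, "
      f"carrier fraction {s['carrier_fraction_pct']:.1f}%")
```

prints

```
carrier rate 10.6%, Fisher p = 0.00527, corrected threshold 0.0014
21 heteroplasmic calls, carrier fraction 27.1%
```

The first line reproduces a typical rare-burden comparison: 10.6% of cases
versus 4.7% of controls carry a rare variant in the gene, nominally
significant (p ≈ 0.005) but short of the 37-gene corrected threshold. The
second line shows the simulated cohort's heteroplasmy load after full
pileup-level calling (at the default Poisson rate, roughly a third of
samples carry at least one heteroplasmy ≥ 10%).

The same stages are available from the shell:

```bash
mitocohort simulate --seed 7 --out-dir bundle/
mitocohort analyze --bundle bundle/ --seed 7 --out-dir report/
```

which writes `calls.tsv`, per-sample VCFs, `haplogroups.tsv`, `burden.tsv`,
`heteroplasmy.tsv`, `copynumber.json` and a reproducibility manifest.

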