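# Methods

`mitocohort` implements a cohort-scale analysis of mitochondrial DNA (mtDNA)
point variation and abundance in post-mortem brain tissue, of the kind used
to ask whether inherited rare variants, somatic heteroplasmy, or mtDNA
content differ between neurodegenerative-disease and control brains. The
pipeline starts from per-base read pileups over the rCRS mitochondrial
reference (upstream alignment, duplicate marking, NumtS removal and
off-target read recovery are out of scope) and produces variant calls,
haplogroup assignments, rarity classes, case-control burden tests,
heteroplasmy summaries, and relative copy-number comparisons.

## Genome model

Coordinates are 1-based inclusive on the 16,569 bp rCRS (NC_012920.1). The
genome is circular; the only origin-wrapping feature is the D-loop control
region (16024–576). The packaged gene map carries the 37 genes (13 protein,
22 tRNA, 2 rRNA) with their OXPHOS complex assignments (I: the seven ND
genes; III: MT-CYB; IV: MT-CO1–3; V: MT-ATP6/8). Overlapping genes
(MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4, MT-TI/MT-TQ) are permitted: a position
reports all overlapping gene names but exactly one *primary region* under
the precedence dloop > tRNA > rRNA > protein > other_noncoding, so region
percentages over any variant set sum to 100%. The precedence order is a
package convention: published region breakdowns do not disambiguate how
overlapping annotations were resolved, and the D-loop-first rule matches the
usual control-region reporting.

Reference bases are optional. The real rCRS sequence can be supplied as a
FASTA (`MitoGenomeModel.default(reference_fasta=...)`); the simulator and
test-suite use a deterministic *synthetic* stand-in sequence
(`synthetic_reference`), pinned to the marker table's reference alleles at
marker positions. Pileup rows carry their own reference base, so calling
does not depend on which sequence backs the model; the model's bases are
used only for consistency checking (mismatching sites are skipped with a
warning).

## Variant calling and heteroplasmy

For each non-reference allele at a site the heteroplasmic fraction in
percent is

    HF = 100 · v / d

with v the variant-supporting reads and d the site depth for SNVs and
deletions, or the 5′-flanking read count for insertions (insertions are
anchored to the 5′ adjacent base, deletions represented per deleted base;
indels are expected left-normalised on input). Sites qualify when mean base
quality ≥ 25 and depth ≥ 5; both thresholds are inclusive and configurable.
Zygosity is a pure function of HF: below 10% the site is treated as
homoplasmic for the reference allele and the minor allele is dropped (an
optional `keep_low_level` flag retains it tagged `low_level`, excluded from
all cohort statistics); above 90% it is homoplasmic for the alternate;
HF of exactly 10 or 90 is heteroplasmic — the homoplasmic intervals are
open, their complement closed. The quality threshold is applied to the
site-mean Phred score; per-allele mean quality is an equally defensible
reading of a scalar "QS ≥ 25" rule and can be emulated by supplying
per-allele pileups.

## Haplogroups and rarity

Haplogroup assignment is a transparent marker-overlap scorer rather than a
phylogenetic-tree traversal: for each candidate haplogroup with marker set
M and a sample's homoplasmic-alternate variant set S,

    score = (|S ∩ M| / |M| + |S ∩ M| / |S|) / 2

i.e. the Kulczynski mean of marker recall and precision. Ties prefer the
haplogroup with more defining markers, then the lexicographically smaller
label. The packaged marker table is a deliberately simplified curated set
for nine major European haplogroups; a full Phylotree-derived table can be
loaded through the same TSV interface, which is the recommended route for
real data.

Population allele frequencies are per-individual carriage fractions within
a haplogroup (MpAF): the fraction of reference-panel individuals of
haplogroup h carrying allele a at position p, independent of read support.
A variant is *novel* when absent from the panel and from every supplied
catalog, *rare* when MpAF < 0.05 within the sample's haplogroup (exactly
0.05 is common — "less than 5%" read strictly), else *common*. Rarity of
heteroplasmic calls is classified by allele identity, but burden analyses
restrict to homoplasmic variants by default, mirroring how rare-variant
carriage is defined for inherited variation.

## Burden testing

A sample carries a unit (variant, gene, or respiratory complex) when it has
at least one qualifying call there; qualifying is a filter on zygosity,
rarity, and an optional age stratum (young-onset AD: death < 60; young
DLB-PD: death < 70 — both configurable predicates). Carrier counts form a
2×2 table tested with the two-sided Fisher exact test under the
point-probability rule: conditional on both margins, p is the sum of
hypergeometric point masses not exceeding the observed table's (with the
customary 1 + 1e-7 relative gate against floating-point noise, as in R).
Tables with a zero margin return p = 1 with a warning. The gene-burden
family is the 37 mtDNA genes, so the default Bonferroni threshold is
0.05/37 ≈ 0.0014.

Heteroplasmy-age association uses the Poisson log-linear model
count ~ Poisson(exp(β₀ + β₁·age)), fitted by IRLS (statsmodels GLM,
relative tolerance 1e-8, ≤ 100 iterations) with a Wald two-sided p for β₁.
The Wald test is the conventional default; the model family alone does not
dictate Wald versus likelihood-ratio. All-zero counts leave the slope
undefined and are flagged rather than fitted.

Pathogenicity scores (MutPred/PolyPhen-style, in [0,1]) are consumed as an
optional input column, never computed; group comparisons aggregate to
per-sample means and use the Mann-Whitney test.

## Copy number

Relative mtDNA copy number is mean mtDNA depth over all 16,569 positions
(zero-depth positions included — the definition is a whole-genome mean)
divided by mean on-target exome depth, taken as a per-sample scalar input.
Group comparisons use the two-sided Mann-Whitney test: full enumeration of
group assignments when the smaller group has ≤ 8 samples (tie-aware via
average ranks), otherwise the normal approximation with tie and continuity
correction. Whether published ratio comparisons used raw or log ratios is
immaterial for a rank test (and the `log_ratios` flag demonstrates the
invariance). Age association uses Spearman rank correlation with
average-rank ties; p is by exact permutation enumeration for n ≤ 9 and the
t-approximation otherwise.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with full ground
truth for recovery testing:

* **Cohort**: group sizes and age-at-death normals default to the brain
  cohort the pipeline targets (AD 282 at 78.1 ± 11.6, CJD 181 at
  55.1 ± 19.2, Control 351 at 78.1 ± 12.0, DLB-PD 89 at 75.1 ± 8.5,
  FTD-ALS 236 at 64.4 ± 11.5, young controls 110 at 41.4 ± 9.7, other
  disorders 114 at 72.7 ± 16.7; ages truncated at 1 year), with the
  reported female fractions.
* **Germline**: each sample draws a haplogroup from a roughly-UK mixture,
  carries its marker homoplasmies plus Poisson(16) private homoplasmies,
  putting total homoplasmies near the observed ≈ 23 per sample.
* **Heteroplasmy**: per-sample somatic count is Poisson with mean 0.39 —
  chosen so the expected fraction of samples with ≥ 1 heteroplasmy,
  1 − e^(−0.39) ≈ 32.3%, matches the observed carrier fraction — optionally
  age-dependent on the log scale (count ~ Poisson(exp(β₀ + β₁·age))).
  Fractions follow Beta(1.2, 2.4) rescaled to [0.10, 0.90]; the Beta shape
  is a documented convention (no published HF distribution exists to match),
  skewed toward lower fractions. Positions are placed by region with
  weights 55.7% D-loop / 33.3% protein / 4.8% rRNA / 6.2% tRNA, the
  observed regional mix of brain heteroplasmies; uniform placement is
  available.
* **Sequencing**: per-sample mean pileup depth is normal 289 ± 169.8
  (floor 66) scaled by the sample's copy-number ratio relative to the
  cohort mean; per-site depth is Poisson; variant reads are
  Binomial(depth, HF); errors hit non-truth alleles at 1e-3 per read; mean
  base quality is normal 36.8 ± 0.25.
* **Copy number**: per-group log-normal ratios, parameterised by
  natural-scale mean/sd. CJD splits into 40 vCJD-like samples
  (mean 4.14, sd 2.96) and the rest (10.03, 7.67) — both published values;
  the remaining groups have no published means, so controls and
  non-AD groups use mean 10, sd 5 and AD mean 8, sd 5 as conventions that
  carry a disease effect of plausible size. Emitted depth summaries satisfy
  E[mt mean / nuclear mean] = true ratio, exactly so under a zero-noise
  configuration.
* **Determinism**: every sample owns a random stream keyed by
  (seed, CRC32(sample id)), so identical seeds give byte-identical bundles
  and cohorts are reproducible under subsetting.

What the generator does *not* emulate: NumtS contamination, alignment and
mapping artefacts, strand bias, site-specific error spectra, linkage between
private variants and haplogroup (privates are uniform), region-dependent
copy number (e.g. the cerebellum composition confound), or any real HF
distribution shape. Passing recovery tests therefore demonstrates that the
pipeline's estimators and classifiers are correct under the stated
statistical model, not that real-data artefacts are handled.

## Numerical and test-design choices

* Exact-test implementations are validated against independent oracles:
  integer-arithmetic hypergeometric enumeration for every 2×2 margin class
  with total ≤ 60; full assignment enumeration for Mann-Whitney with
  n₁+n₂ ≤ 12 (with and without ties); full permutation enumeration for
  Spearman up to n = 8.
* Null calibration of the gene-burden machinery uses 2000 simulated null
  cohorts (case/control 282/344, one gene-level test per cohort with
  carrier probabilities cycling over 0.1–0.5); the rejection rate at 0.05
  is required to sit inside the binomial 99% band around the nominal level.
  Exact conditional tests are conservative by discreteness, so mid-range
  carrier probabilities and paper-scale group sizes are needed for the
  nominal rate to be achievable at all; the analytic rejection rate under
  this design is ≈ 0.045.
* The end-to-end recovery check runs at mean depth 1000: near the 10%/90%
  boundaries, zygosity misclassification is a binomial tail event whose
  probability is non-negligible at depth ≈ 300, so the zero-misclassification
  assertion (outside HF (0.08, 0.12) ∪ (0.88, 0.92)) is made at a depth
  where the aggregate misclassification probability is < 1e-3. HF-interval
  recovery at the default depth of 289 is reported by the acceptance
  script instead.
* Report precision: p-values print at 3 significant figures, HF at one
  decimal; internal computations are unrounded.

## Problem sizes

The default simulated cohort is the full 1363-sample structure and runs the
complete pipeline (generation, calling, summaries) in a few seconds; the
test suite's property sweeps (exhaustive Fisher enumeration to total 60,
2000-cohort null calibration, 500-replicate power checks) complete in well
under a minute in total.

## Known limitations

* The marker-overlap classifier is shallower than Phylotree-walking tools;
  with the packaged nine-haplogroup table it resolves major clades only.
* Insertions use the 5′-flank denominator as supplied in the pileup; no
  re-alignment or flank recomputation is attempted.
* Copy-number estimates inherit whatever capture biases the upstream exome
  pipeline has; the ratio is relative, not genomes-per-cell.
* Multi-allelic sites are treated per alternate allele independently; HFs
  at a site are not constrained to sum to ≤ 100%, matching pileup-level
  evidence rather than a genotype model.
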