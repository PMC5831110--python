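# Methods

`coexmeta` implements a seed-gene guilt-by-association analysis for expression
compendia assembled from many independent studies. The motivating use case is
ranking genes by co-expression with *MS4A1* (CD20) across pooled diffuse large
B-cell lymphoma microarray cohorts, but every stage is generic: any seed gene,
any number of batches, any probe-to-gene map.

## Model and procedure

**Batches.** A batch is a platform x experiment grouping. All association
statistics are computed strictly within batches and only then pooled, so that
platform and study effects never masquerade as co-expression. No batch-effect
correction of the expression values themselves is attempted — the
meta-analytic design is the batch handling.

**Quality control.** Two per-batch filters precede the analysis:

1. *Duplicate arrays.* Each sample's expression vector is serialized at fixed
   precision (6 decimals) and MD5-hashed; among samples with identical
   digests the first in column order is kept. Hashing the canonical numeric
   serialization rather than raw files keeps the semantics format-independent.
2. *Low-quality arrays.* The first principal component (PCqc) of the sample
   correlation matrix dominates well-behaved expression data — the shared
   gene-baseline profile makes every pair of arrays highly correlated, and
   PC1 typically explains 80–90% of the variance of that matrix. Each sample
   is scored by the Pearson correlation of its expression profile with the
   PC1 metagene (the PCqc-weighted combination of samples), and samples with
   score strictly below 0.8 are removed; a score of exactly 0.8 is kept.
   An alternative scoring — correlating each sample's *row of the correlation
   matrix* with PCqc — is available behind `score_mode="corr-rows"`, but it is
   not the default: when PC1 is dominant, the rows and the eigenvector are
   both nearly constant, their Pearson correlation is then driven by noise,
   and on homogeneous batches of several hundred arrays the score collapses
   (~0.3) for perfectly good samples. The profile-based score is stable at
   all batch sizes and separates injected pure-noise arrays (score ~0) from
   intact ones (score ~0.93 at default noise levels) by a wide margin.

**Association.** The seed gene's probes are collapsed by the arithmetic mean
within each batch. Every probe is then correlated (Pearson r) with that seed
profile over the batch's kept samples. Probe-level association is the
default (matching how ranked probe lists are reported); a gene-level mode
collapses all genes first. Correlations are Fisher-transformed, z = atanh(r)
with SE = 1/sqrt(n-3); |r| = 1 is clipped to 1 - 1e-12 so degenerate cases
stay finite.

**Fixed-effect pooling.** Batch estimates are combined by the generic
inverse-variance method: weights w_i = 1/SE_i^2 = n_i - 3,
z̄ = Σ w_i z_i / Σ w_i, SE_pooled = 1/sqrt(Σ w_i), statistic = z̄/SE_pooled
referred to the standard normal (two-sided p). Probes missing in a batch
(absent from the platform, or zero variance) contribute nothing to that
batch's sums — complete-case pooling, which is what allows mixed platforms.
The Fisher-z scale is the standard variance-stabilizing choice for pooling
Pearson correlations; no random-effects or heterogeneity modeling is done.
Ranking is by signed statistic descending (positive co-expression first) with
lexicographic tie-breaks for determinism; the seed's own probes trivially
attain r = 1 and are excluded from top-k reporting. Negatively associated
probes are written to a separate report.

**Permutation FDR.** Significance is calibrated by a multivariate permutation
test: the seed profile is independently shuffled within every batch
(destroying seed association while preserving batch structure and all
gene–gene covariance) and the full meta statistic is recomputed for all
features, B times (default B = 1000). Over candidate thresholds t (the sorted
observed statistics), V_b(t) counts null statistics ≥ t in permutation b and
V*(t) is the ceil(confidence·B)-th order statistic of {V_b(t)}; the chosen
threshold t* is the smallest t with V*(t) ≤ γ·R(t), where R(t) is the number
of observed statistics ≥ t, γ the FDR target (default 0.01) and the
confidence default 0.99. This is the order-statistic ("with confidence
1-α, the false-discovery proportion is at most γ") construction; shuffling
only the seed rather than all genes is the cheapest exchangeable null for the
seed-association question. Selection is one-sided positive by default, with a
two-sided |statistic| option.

**Enrichment and prioritization.** Over-representation of the selected genes
in GMT collections uses the hypergeometric upper tail, conditioning the
universe on genes actually measured in ≥1 batch after QC (not the whole
genome), with multi-probe genes counted once; p-values are BH-adjusted across
sets. A nine-category single-assignment pathway annotation (BCR signaling,
cytoskeleton regulation, DNA repair and cell cycle, histone modification,
immune regulation, metabolism, protein processing, RNA processing, signaling
protein) is supported as a table-driven map. Prioritization joins the
selected genes (in association order) to a local drug–gene interaction
snapshot; genes in any exclusion set (e.g. BCR-signaling members, or targets
already in trials for the disease) are flagged with the set name as reason,
and retained genes get priority ranks.

**Clinical statistics.** Cohort composition is summarized as
availability/level percentages with round-half-up at one decimal (plus an
integer form for prose). Subtype expression differences use Kruskal–Wallis on
midranks with tie correction. Expression is dichotomized at the median by
default (values strictly above → "high", ties → "low"; other quantiles
selectable) — the cut-point is a genuinely open choice and the median is the
least informative default. Survival curves are Kaplan–Meier product-limit
estimates; two-group comparisons use the standard log-rank O/E machinery
with simultaneous risk-set accounting of ties, chi-square (O1−E1)²/V, and the
hazard ratio estimated as (O1/E1)/(O2/E2) with CI
exp(ln HR ± z·sqrt(1/E1 + 1/E2)). The O/E estimator (rather than Cox
regression) is used because the HRs are attributed to the log-rank procedure;
stratified comparisons run per treatment-arm × subtype cell.

## Synthetic compendium generator

The generator provides known ground truth for every stage. Gene-level
expression in batch b is

    x[g, j] = 8 + loading[g] * f[j] + shift[b, g] + module[g, j] + eps[g, j]

on a log2-like scale resembling RMA output. `loading ~ N(0, common_factor_sd²)`
(default 2.0) is a gene profile shared by all samples; `f[j] = 1 +
sample_factor_sd·ξ` (default exactly 1) expresses it per sample;
`shift ~ N(0, batch_shift_sd²)` (default 0.5) is a per-batch per-gene offset;
`eps ~ N(0, noise_sd²)` (default 0.8). With the default `sample_factor_sd = 0`
the shared profile drives the sample correlation matrix — every array pair
correlates at about loading-variance / (loading-variance + noise variance +
batch-shift variance) ≈ 0.87, putting the PC1 variance fraction in the
0.85–0.87 range — while all gene–gene population correlations remain exactly
zero, so unplanted genes are genuinely null for the seed-association test.

Module genes are exact scaled copies of the seed's per-sample deviation:
deviation_g = ρ·e_seed + sqrt(1−ρ²)·ε with ε independent at the same noise
scale, giving population Pearson correlation exactly ρ (negative ρ flips the
sign). Outlier arrays are replaced wholesale by N(8, outlier_sd²) noise with
no shared profile, which pins their PCqc score near zero. Probe multiplicity
replicates the gene signal per probe with a per-probe offset and jitter
(`probe_noise_sd`, default 0.1), which attenuates probe-level correlations by
under 1% at default settings.

Defaults are the stock study conditions: 3 batches of 500/400/300 samples
(~1200 total), 2000 genes, a 50-gene module planted at correlations evenly
spaced in [0.5, 0.9], 6 injected outliers. Clinical tables draw
cell-of-origin labels at (0.352, 0.493, 0.155) for ABC/GCB/unclassified and
treatment arms at (0.233, 0.719, 0.048) for CHOP/R-CHOP/other, echoing a
large pooled lymphoma cohort; survival is exponential with hazard
baseline_hazard·exp(Σ log-HR effects) (baseline 0.02/month) and independent
exponential censoring (rate 0.01/month; 0 disables censoring — allowed even
though censoring is normally present, so that no-censoring calibration runs
are expressible).

### What the simulator does not emulate

Real arrays have heavy-tailed noise, probe-sequence effects, correlated gene
modules beyond the planted one, platform-specific probe content, and
confounding between batch and biology. Passing tests on this generator
demonstrate that the statistical machinery is correct under its stated model
— exact planted correlations, exchangeable nulls, exponential survival — not
that the pipeline is robust to every artifact of real data. In particular the
FDR-control results rely on the seed-shuffle null being exchangeable, which
real batch confounding could violate.

## Numerical choices and degenerate inputs

- |r| = 1 → clipped to ±(1 − 1e-12) before atanh.
- Zero-variance probes within a batch → missing for that batch
  (complete-case pooling); a zero-variance *seed* profile is an error.
- Ranking ties → lexicographic on gene symbol then probe id.
- PCqc sign → fixed so the mean loading is nonnegative; a fully constant
  score pair (homogeneous rank-one batch) scores 1.0 by convention.
- QC threshold boundary → strictly-less-than removal: a score of exactly 0.8
  is kept.
- Median dichotomization ties → "low".
- p-values floored at the smallest positive double to keep downstream logs
  finite.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the config objects; identical seeds give byte-identical outputs.

## Problem sizes used in the test and acceptance runs

Unit tests use compendia of 40–300 genes and tens of samples. The
operating-characteristic suites use the stock conditions: 100 global-null
compendia (2000 genes, batches of 100/80/60) at B = 500 permutations for FDR
control; 100 default-size compendia for the QC band and outlier sensitivity;
the stock fixture with B = 200 for end-to-end recovery; 4000 simulated
patients for hazard-ratio recovery. `scripts/acceptance.py` re-runs the same
computations with 20 QC replicates and 30 null-FDR replicates at B = 300.

## Known limitations

- Fixed-effect pooling assumes a common underlying correlation across
  batches; heterogeneity (I², Q, random effects) is deliberately out of scope.
- The permutation null shuffles only the seed; it calibrates seed-association
  inference and nothing else.
- The O/E hazard-ratio estimator is biased toward 1 for large effects
  (simulated true HR 2 with all events observed estimates ≈ 1.86), so its
  tight large-sample confidence interval covers the estimand of the O/E
  procedure rather than the data-generating HR; confidence intervals use the
  classic 1/E1 + 1/E2 variance approximation.
- Enrichment is over-representation only; no ranked (walk-statistic) GSEA.
- The package accepts already-normalized matrices; raw-array preprocessing
  (e.g. RMA) is upstream of its scope.
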