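# Methods

## The SEV model

A stochastic epigenetic variation (SEV) is a subject-private epimutation:
at a single CpG probe, one subject's methylation fraction (beta value) is
an *extreme* outlier relative to a reference population. Per probe, the
reference cohort's first and third quartiles are computed as Tukey hinges
(the convention behind R's box-and-whiskers statistics: the hinges are
medians of the lower and upper halves of the sorted data, the median
included in both halves when n is odd), and the fences are

    lower = Q1 − 3·IQR,   upper = Q3 + 3·IQR,   IQR = Q3 − Q1.

The multiplier 3 targets the "extreme outlier" regime of the boxplot
convention (1.5 would flag ordinary biological spread). A value is called
a SEV iff it lies **strictly** beyond a fence — ties at the fence are not
outliers, consistent with whisker semantics. Fences are deliberately not
clipped to [0, 1]: a fence outside the feasible beta range simply cannot
yield calls on that side. Probes whose reference IQR is zero keep their
collapsed fences (any strict deviation is a call) but are tallied
separately for diagnostics. Linear-interpolation quantiles are available
(`quantile_method="linear"`) but all reported results use hinges.

Three reference modes mirror common practice: the internal control cohort
(members called against fences from the whole reference including
themselves — "pooled" — or against leave-one-out fences), an external
cord-blood population, and a general-population whole-blood panel. For a
reference member, leave-one-out counts are always ≥ pooled counts, because
a member's own extreme values can only widen the pooled fences; both modes
are provided and pooled is the default. Subjects with zero calls get
`log(n + 1) = 0` with an explicit flag; everything else uses the natural
log of the count.

## Regional enrichment

Per subject, SEV over-representation in a region with K probes is tested
with the hypergeometric upper tail P(X ≥ k) for X ~ Hypergeom(N, K, n),
where N is the post-QC probe count and n the subject's genome-wide SEV
count. The tail is computed from log-weights built by the stable
pmf(j+1)/pmf(j) ratio recursion, normalised by their own logsumexp — this
keeps relative error near 1e-13 even for supports of thousands of terms,
where a gammaln-anchored sum drifts to ~1e-10. Sliding windows default to
5 kb width with 50% overlap (the window geometry is a package choice;
5 kb matches the tiling resolution used for region summaries). Windows or
regions containing no probes are skipped and do not enter the Bonferroni
factor, which is applied within subject across the tested regions of one
region set. Call direction is ignored: clustered departures in either
direction indicate a localised defect, as in an imprinting-control region
losing or gaining methylation.

## Quality control

Probes flagged for SNP overlap, sex-chromosome location or rare-variant
overlap are removed first (attribution to the first matching criterion in
that fixed order). Greedycut then iteratively removes whichever probe or
sample has the highest fraction of unreliable entries — unreliable iff the
detection p-value is *not below* 0.05, read literally as p ≥ 0.05 — with
ties broken probe-before-sample, then lexicographically. The stopping rule
is a plain threshold on the maximum remaining unreliable fraction
(default 0: remove until fully reliable) rather than a ROC-style curve;
the simpler rule is transparent and configurable.

## Phenotype dimensions (FAMD)

Factor analysis of mixed data: continuous columns are standardised to zero
mean and unit population variance; each categorical is expanded to level
indicators divided by the square root of the level frequency and centred.
The SVD of the combined matrix gives sample scores (variance of dimension
j equals its eigenvalue) and variable loadings. Under this weighting a
continuous column contributes inertia 1 and a categorical L − 1, so the
total inertia is #continuous + Σ(L − 1), and on an all-continuous table
FAMD is exactly standardised PCA. Dimensions are oriented so the
largest-magnitude loading is positive (deterministic sign). Season of
birth is treated as a plain 4-level categorical (no cyclic encoding).
Dimension–trait association uses Pearson correlation for continuous
traits, point-biserial for binary, and the correlation ratio (with a
one-way ANOVA p) for multi-level categoricals; maximum-likelihood
polyserial/polychoric estimation was deliberately not used — it is out of
proportion to the correlogram's descriptive role, and the divergence is
confined to the multi-level entries of that table. Dimensions are screened
against case/control status by per-dimension logistic regression (IRLS);
perfect separation is reported with a documented p floor (1e-16) instead
of raising.

## Association and diagnostics

Per reference mode, one OLS fit of log(SEVs) on all 10 dimension scores
jointly plus chip-batch indicators; per-dimension t-test p-values are
combined across modes with Fisher's method (−2·Σ ln p ~ χ² with 2k df;
p-values floored at 1e-300 first) and Bonferroni-corrected over the 10
dimensions. The Fisher combination assumes independence across modes; the
modes share subjects, so the combination is anti-conservative. This is a
deliberate, documented choice (the three estimations are treated as
quasi-independent corroborations); its practical effect is visible in the
null calibration below. The EWAS-lite stage is a plain per-probe OLS of
beta on group plus covariates with classical standard errors — it exists
for covariate-adjustment demonstrations and for the genomic inflation
factor λ = median(χ²_obs)/median(χ²₁) ≈ median/0.4549, not as a moderated
differential-methylation method. The sample-size utility implements the
two-group normal approximation n = ⌈2(z_{1−α/2} + z_power)²·σ²/Δ²⌉ with
defaults α = 1e-7, power 0.95, aimed at a minimum detectable methylation
difference of 10%.

## The synthetic cohort generator

The generator emulates a 450K-style cord-blood study at desk scale.
Defaults define the study conditions: 41 reference (naturally conceived)
and 23 case subjects, 10,000 probes over 5 chromosomes, 100 genes
(≥ 5 contiguous probes each), 8 imprinted DMRs (≥ 8 contiguous probes, so
a clustered defect is enrichable), a mean epimutation rate of 20 per
subject, 2 chip batches with beta-scale shift SD 0.01, detection-p
unreliable fraction 0.001, and four latent phenotype factors.

* **Probe baselines** are bimodal: ~45% hypomethylated (mean ≈ 0.1), ~45%
  hypermethylated (≈ 0.9), 10% intermediate — the canonical shape of array
  beta distributions. Subject values are Beta(m·ν, (1−m)·ν) with
  precision ν = 100, matching the unimodal-around-mode spread of array
  betas without modelling intensities.
* **Injected epimutations**: each subject receives Poisson(rate) calls at
  eligible (unflagged) probes; the injected value is the midpoint between
  the fence and the nearer of {0, 1} on a feasible side (side uniform when
  both are feasible), guaranteeing a strict outlier regardless of quantile
  convention. With a phenotype effect configured, the subject's rate is
  rate·exp(Σ slope_f·z_f), linking latent factors to SEV burden.
* **Exactness guarantee**: every non-injected value is rejection-resampled
  from its probe's beta distribution until it lies strictly inside the
  reference-derived fences, with fences recomputed until stable. Calling
  against the uncontaminated reference therefore recovers the injected set
  exactly — sensitivity 1, zero background calls — which turns downstream
  checks into exact tests rather than approximate ones.
* **Imprinting defect**: one optional subject gets mid-range aberrant
  values (≈ 0.5 shifted away from the probe's mode, SD 0.02) across every
  probe of one DMR.
* **Phenotypes**: birth weight, centiles, gestational age, parental
  weights/BMI, gestational weight gain, six cell proportions (non-negative,
  summing to 0.97), and categoricals (sex, smoking, cesarean, folate
  supplementation, parity, season of birth) are noisy functions of at most
  four latent factors, with factor 1 deliberately dominant so the leading
  FAMD dimension tracks it; season of birth is a quartile cut of factor 3
  plus noise. Case/control status is assigned by design, independent of
  everything else — the null case-control comparison is true by
  construction.
* **Reproducibility**: one RNG stream per logical component (annotation,
  betas, epimutations, phenotypes, detection-p, external references) is
  split from the master seed, so changing the epimutation rate does not
  perturb baseline betas; identical config + seed is bit-identical.
  Positions are 1-based with ≥ 100 bp spacing (manifest convention); all
  interval files are 0-based half-open BED.

What the generator does *not* emulate: probe type I/II chemistry,
intensity-level noise and normalisation artefacts, genotype effects under
probes, cell-composition effects *on methylation* (composition enters only
as a phenotype), and confounding between phenotypes and probe-level
methylation. Consequently the null EWAS here is genuinely null: λ sits
near 1, with a mild upward bias (typically 1.05–1.1 at 64 samples)
because injected epimutations make per-probe residuals heavy-tailed, which
inflates the median test statistic slightly under classical OLS. The
generator cannot reproduce inflation caused by real confounding — a
passing λ check shows the diagnostic is calibrated, not that real studies
are clean. Likewise, passing recovery tests show the calling machinery is
exact under the model's assumptions, not that real cohorts are free of
background outliers.

## Problem sizes and calibration results computed by the suite

The acceptance experiments use: 200 random small matrices for the
fence/call oracle; one 64-subject × 10,000-probe cohort for exact
recovery; exhaustive hypergeometric enumeration to N = 12 plus 100 PMF-sum
spot checks; 100 cohorts (4,000 probes, 6 DMRs) for the imprinting-defect
screen; 200 null association replicates at full study scale (the reported
rate is the fraction of dimension-level rejections among 2,000 tests —
per-replicate family-wise rejection runs above nominal, the expected
footprint of the anti-conservative Fisher combination documented above);
100 cohorts for the planted-effect power experiment; and a 30-pair
replicate-concordance experiment at 2,000 probes. Sizes were chosen so the
whole suite runs in a few minutes on a single core while keeping every
Monte-Carlo bound well-separated from its threshold.

## Known limitations

* Pooled internal calling slightly shrinks sensitivity relative to the
  uncontaminated reference (a subject's own epimutations widen the pooled
  fences); the leave-one-out mode removes this at higher cost.
* The Fisher combination across shared-subject modes is anti-conservative
  at the family-wise level (see above); treat cross-mode combined
  p-values as corroborative, not as exact error rates.
* Greedycut's threshold stopping rule is simpler than ROC-based variants;
  with very high unreliable fractions it can cascade.
* FAMD here performs no rotation, supplementary projection or missing-data
  imputation; tables must be complete.
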