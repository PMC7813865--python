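# Methods

## Scales and transforms

Methylation enters as β = methylated/(methylated+unmethylated) signal,
bounded in [0, 1] and strongly heteroscedastic near the boundaries. All
hypothesis tests on means run on M = log₂(β′/(1−β′)) with
β′ = clip(β, ε, 1−ε), ε = 10⁻⁶; the clip bounds |M| at ≈ 19.93 while
preserving order, so the transform is finite for boundary β. Effect
sizes are reported as Δβ — the difference of group mean β — because β
differences are the interpretable unit for methylation. Δβ is computed
on quantile-normalized β (normalization happens before any testing);
the choice of normalized rather than raw β for the effect size was an
open design point and is the package's own convention.

Variance tests (the DVP route) run on β, not M: the differential-
variability literature formulates outlier detection on the bounded
scale, and β-scale variances are what the boxplot-style diagnostics
show.

## Quantile normalization

Every sample is mapped onto the across-sample mean quantile curve;
within-sample ranks are preserved. Ties receive the mean of the target
quantiles over their rank span (deterministic); columns with missing
entries are mapped through interpolated fractional ranks against the
same reference curve. The operation is idempotent to 1e−10, which the
suite asserts. Single-sample input is a logged no-op.

## Moderated t (empirical-Bayes variance shrinkage)

Per feature g, ordinary least squares of the M-value (or log-expression)
row on a sample × covariate design X gives the coefficient β̂_g, residual
variance s²_g and residual df d = n − rank(X). The s²_g are modeled as
draws from a scaled-F prior, s²_g ~ s₀²·F(d, d₀); hyperparameters are
estimated by matching the first two moments of log s²_g:

    e_g   = log s²_g − ψ(d/2) + log(d/2)
    ψ′(d₀/2) = var(e) − ψ′(d/2)           (solved by Newton on ψ′)
    s₀²   = exp( mean(e) + ψ(d₀/2) − log(d₀/2) )

where ψ, ψ′ are the digamma and trigamma functions. When the observed
log-variances are no more dispersed than chi-square sampling noise
(var(e) ≤ ψ′(d/2)) the prior df is infinite and s₀² is the arithmetic
mean of the s²_g — the limit in which every feature is assigned the
common variance. The posterior variance is the df-weighted blend
s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d), and the moderated statistic
t̃_g = β̂_g/(s̃_g√v) (v the contrast's unscaled variance) is referred to
t with d₀ + d df (normal when d₀ = ∞). The implementation is checked in
the suite against the Bioconductor reference (limma `lmFit`+`eBayes`,
run through Rscript) at 1e−8 on a seeded matrix with a covariate
column, and against its own closed-form limits (d₀ = 0 reduces exactly
to the pooled two-sample t; constant variances give full shrinkage).

Covariate handling: age and sex enter as additive design columns, not
interaction terms — additive adjustment is the conventional reading for
demographic confounders. Samples with missing covariate values are
excluded with a logged count rather than imputing or silently dropping
the covariate; a covariate constant across retained samples is dropped
(it would be collinear with the intercept). Pairing (mono/co-culture)
enters as fixed-effect pair indicator columns; with k pairs the
residual df is k − 1, so at least two complete pairs are required.

## DMP criterion

called ⇔ |Δβ| ≥ 0.1 and p < 0.01 (raw, not FDR-adjusted). The joint
effect-size + significance filter is strictly more conservative than
either alone: under the global null the suite measures a called
fraction far below 0.1% at 2 000 probes and 8–10 samples per group. A
flag switches the p criterion to BH-adjusted q for users who want FDR
semantics.

## DVP criterion (iEVORA)

Per probe, Bartlett's two-group statistic on β

    T = [(N−k)·ln s_p² − Σ(nᵢ−1)·ln sᵢ²] / C,   k = 2,
    C = 1 + (1/(3(k−1)))·(Σ 1/(nᵢ−1) − 1/(N−k)),

with p from χ²(k−1), BH FDR across probes, and q < 0.05 required. Among
those, a two-sample t-test must reach p < 0.05 — the regularization that
protects the variance test from single-outlier artifacts. Called probes
are ranked by t p ascending (ties: Bartlett q, then probe id).
Direction is the sign of the group mean β difference; the convention is
deterministic and matches the outlier direction in outlier-driven
variance models. Welch's t is the default (variance heterogeneity *is*
the tested hypothesis); the pooled variant is selectable. Zero-variance
probes are excluded from the FDR with a logged count. Setting the t
threshold to 1 switches regularization off and reduces the caller to
Bartlett-FDR alone, which the suite asserts.

### Power ceiling of the t-regularization

The regularizing t-filter imposes a hard power ceiling against
fixed-fraction outlier alternatives, which the test suite measures
honestly rather than hiding. If a fraction f of n disease samples shift
by any amount s (two-point mixture) against a tight control group, the
pooled two-sample t is *independent of s*:

    t = √( f·(n−1) / (1−f) )

(the statistic is affine-invariant and a two-point mixture has only its
proportion as shape). At f = 0.3, n = 10 this is 1.964, below the
two-sided 0.05 critical value 2.101 (df = 18); Welch is further away
(p ≈ 0.08 at df ≈ 9). Hence a 30%-outlier DVP with however large a
shift is systematically rejected by the t-filter: the measured
sensitivity of the caller under that planted model is a few percent,
not a high fraction, and only crosses 50% once f ≥ 4/n. This is a
property of the iEVORA design (the filter exists precisely to demand a
mean shift alongside the variance signal), not an implementation
artifact: the Bartlett stage alone recovers essentially all planted
DVPs (q ≪ 0.05), as the per-probe outputs show.

## Set algebra and enrichment

Progression components are computed within each direction:
MM∖(MGUS∪SMM), (SMM∩MM)∖MGUS, MGUS∩SMM∩MM; probes with conflicting
directions across stages are excluded and logged (accumulative change
is direction-consistent by definition — the conflict rule is a package
decision). Disjointness and union ⊆ MM are asserted on every run.

Context enrichment builds, per category level, the disjoint 2×2 of
query vs background∖query membership; the odds ratio uses the
Haldane–Anscombe +0.5 correction when any cell is zero so log OR is
always finite, and p is Fisher's exact two-sided value (verified in the
suite against exhaustive enumeration of all tables with the observed
margins). The background defaults to all probes surviving QC filtering;
the query must be a proper subset.

Nearest-gene assignment takes the minimum |probe − TSS| on the same
chromosome, signed negative upstream relative to strand, equidistant
ties resolved to the lexicographically first symbol.

## Synthetic data generator

The generator emulates the statistical structure of the study design,
not array chemistry:

- **Sampling frame**: groups HD/MGUS/SMM/MM with default sizes
  8/10/8/9 — the study scale for this design.
- **Background**: per-probe baseline from a bimodal mixture on the M
  scale (modes at β ≈ 0.10 and 0.85, probability 0.55/0.45, logit-scale
  sd 0.8), matching the characteristic two-peak β histogram of
  methylation arrays. Per-sample noise is Gaussian on M (default sd
  0.05), i.e. β is logit-normal — the choice that makes the M-scale
  linear model *exactly* Gaussian, so moderated-t behaviour can be
  validated against its own assumptions.
- **Planted DMPs**: the affected groups' mean is moved to β₀ ± Δβ
  (default Δβ 0.25) on the M scale; baselines for planted probes are
  drawn mid-range so the target always has [0,1] headroom (infeasible
  targets raise). Each planted probe takes a stage pattern uniformly
  from {MM}, {SMM, MM}, {MGUS, SMM, MM}, so progression-set recovery is
  testable.
- **Planted DVPs**: round(f·n) samples of each affected group (default
  f = 0.3) are shifted by ±0.4 β; the remaining samples are untouched.
- **Covariates**: age adds 0.01 M-units/year (centred) and male sex
  0.5 M-units on 5% of probes each — small additive confounding that
  the design adjustment must absorb.
- **Annotation**: probes and gene TSSs placed on 5 synthetic
  chromosomes with strictly increasing positions; CGI-relation
  fractions default to Island 0.20, shores 0.10 each, shelves 0.05
  each, open sea 0.50; chromHMM states drawn from a fixed
  quiescent-heavy distribution over the 15 Roadmap labels. An optional
  Island multiplier for planted probes creates recoverable enrichment
  signal.
- **Expression**: genes linked to planted DMPs (via the annotation's
  nearest-gene field) shift by 1.5 log₂ units in affected-stage
  samples, with sign opposing methylation with probability 0.9
  (promoter-methylation repression) and matching otherwise; genes
  claimed by planted probes of conflicting direction carry no defined
  coupling and are left unlinked. Background genes are Gaussian noise
  around a log-scale baseline.
- **RRBS**: per-site Poisson depth (default mean 30) and binomial
  methylated counts at a per-site fraction plus group effects.

All generators are pure functions of (parameters, seed); the suite
asserts bit-identical regeneration and the calibration of realized Δβ
(±0.02 of target at n = 10/group).

What passing tests on this generator do **not** show: robustness to
Infinium I/II probe-type bias, background fluorescence, batch effects,
cell-composition heterogeneity, or non-logit-normal noise. The
generator is a correctness harness for the statistics and the set
logic, not a simulator of raw array artifacts.

## Numerical choices and degenerate inputs

- Trigamma inversion by Newton iteration from x₀ = 0.5 + 1/y,
  tolerance 1e−8; failure to bracket falls back to d₀ = ∞ with a
  logged warning.
- Fewer than two features: no shrinkage basis, classical t with a
  logged note.
- BH FDR is NaN-aware (missing p excluded from m, order restored) and
  capped at 1.
- Zero-variance groups make Bartlett/t p missing (logged), never an
  exception mid-pipeline; constant expression genes are excluded before
  fitting.
- RRBS sites must reach the read threshold in *every* compared group;
  zero-depth sites are removed, not divided by.
- Delimiters are sniffed (tab vs comma) from the header line and
  overridable; missing values are "NA"; probes missing in > 20% of any
  group's samples are dropped with a logged count. Coordinates are
  1-based everywhere except BED export (0-based half-open, start =
  pos − 1).
- The pipeline writes a manifest (config hash, seed, package version,
  SHA-256 of every output); rerunning a config reproduces all files
  bit-identically, asserted in the suite.

## Problem sizes used in the checks

The suite and the acceptance script run on simulated matrices of
500–4 000 probes with the study's group sizes (8–10 per group), 50
replicates for null calibration, 200 planted effects for power
measurement, and 100 replicates for enrichment null calibration —
sizes at which every quantity they measure is stable across seeds while
the whole battery completes in seconds on one core. Scaling the same
code to EPIC dimensions (~850k probes) is linear in probes throughout
(all per-probe statistics are vectorised).
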