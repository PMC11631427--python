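# Methods

## Model and procedure

`libramix` treats the UMI counts of one antigen within one sample as draws
from a two-component negative binomial (NB) mixture,

    P(k) = ω · NB(k | n₁, p₁) + (1 − ω) · NB(k | n₂, p₂),

with the NB parameterized as P(k | n, p) = C(k+n−1, n−1) pⁿ (1−p)ᵏ, so the
mean is n(1−p)/p and the variance n(1−p)/p² (matching
`scipy.stats.nbinom`). One component captures technical noise — ambient
barcodes and non-specific capture, concentrated at low counts — the other
true binding at higher counts. Each antigen is fitted independently; the
method assumes no cross-antigen pooling is needed because noise structure
varies by antigen and sample.

The pipeline is three stages:

1. **Noise fit.** If negative-control cells exist (cells carrying a known
   control antibody, whose counts against unrelated antigens are noise by
   construction), a single NB is fitted to their counts by maximum
   likelihood, starting from (n, p) = (1, 1) with p clipped to 1 − 10⁻⁶ to
   enter the open domain. That boundary start is deliberate: the simplex
   reaches distant optima from it on every synthetic set tested, and the
   clip merely makes the initial NLL finite.
2. **Mixture fit.** All five parameters (ω, n₁, p₁, n₂, p₂) are optimized
   jointly by minimizing the log-sum-exp negative log-likelihood with
   Nelder–Mead on (logit ω, log n, logit p per component), so constraints
   hold by construction. The control fit only *initializes* the noise slot
   (with ω₀ = 0.1); it never constrains the optimum. Without controls,
   both slots are seeded from a percentile split of the donor counts at
   the (1 − ω₀) quantile — the lower part seeds the lower-median slot, the
   upper part the higher-median slot. Counts are compressed to unique
   values with multiplicities before evaluation, which makes each NLL
   evaluation O(#unique) rather than O(#cells).
3. **Labeling and posterior.** Components are exchangeable during fitting;
   afterwards the component with the higher median is labeled Signal (ties
   broken by higher mean, then by slot order, labeling the second slot
   Signal — any deterministic rule works because a full tie makes the
   labels observationally equivalent). Bayes' theorem then gives
   P_noise(k) = ω_N NB_N(k)/P(k), evaluated in log space, and
   P_signal = 1 − P_noise as its exact complement, so the pair sums to 1
   by construction and neither can be produced by a 0/0.

Note ω is the weight of the *first slot*, not of the noise component per
se; every reported quantity (noise weight, signal fraction) is derived
from the post-hoc labels, which makes results invariant to slot order.
The percentile-split convention — lower partition seeds the *noise* slot —
follows from the higher-median-is-signal labeling rule.

## Preprocessing

Before fitting: cells with more than one distinct heavy chain are removed
(possible multiplets); control cells are identified by normalized
Levenshtein distance between heavy-chain CDR3s and the control reference
CDR3, with denominator max(len(a), len(b)) (symmetric, and consistent with
reading the 0.05 threshold as 95% identity) and an inclusive ≤ 0.05
comparison; and, per antigen and per population, counts strictly above the
99th percentile (linear-interpolation convention; ties kept) are dropped
as outliers, after the control/donor split. Counts below 4 are *retained*
on the denoising path — zeroing them would erase the noise distribution
the model needs — and zeroed only on the LSS path, where they are
conventionally considered unreliable. Cells whose fitted posterior is
wanted but whose count was trimmed as an outlier are still classified
under the fitted model (an extreme count simply gets P_signal ≈ 1).

## Scores and calls

The LSS is computed as published: zero counts < 4, add a pseudocount of 1,
log, center per cell across the antigen panel (CLR), then Z-score per
antigen across cells using the sample (n−1) standard deviation. Both the
pseudocount and the sd convention are configurable because the upstream
pipeline does not print them; the sd choice rescales a column by a
constant and cannot reorder cells. Combined calls require both LSS ≥ 1
and P_signal ≥ 0.9 (thresholds configurable; P_S = 0.5 is the unbiased
alternative), with ≥ at both boundaries.

## Model comparison and stability

Poisson (3 free parameters) and Gaussian (5, on raw counts treated as
reals) two-component mixtures are fitted by the same direct-NLL route with
the same percentile initialization, for comparability, and ranked by
AIC = 2m + 2·NLL and BIC = m·ln(N) + 2·NLL. The Gaussian fit returns a
structured convergence flag instead of raising, since "failed to converge"
is itself a result in a comparison table.

Bootstrap resampling (default 100 iterations, full-size with replacement)
refits the mixture and tracks the mean P_signal over the original counts;
the summary is the SEM of that mean. Downsampling draws subsamples
*without* replacement at each requested size — a subsample, not a
bootstrap of a bootstrap — and summarizes the CV of the BIC and the sd of
mean P_signal per size. A warning (not an error) is emitted for fits on
fewer than 300 observations, where the downsampling analysis shows the CV
of the BIC rising steeply.

## Synthetic data

The generator draws donor counts per antigen from the labeled NB mixture
and control counts from the noise component only; antigens are independent
unless the optional sticky-cell mode adds a shared per-cell gamma
multiplier (mean 1) to emulate cross-antigen correlation from promiscuous
BCRs — an exploratory feature, not a calibrated one. Control CDR3s are the
reference with independent per-position substitutions at rate 0.03,
rejection-capped at ⌊0.05·len⌋ substitutions so every control stays within
the 95%-identity split; donor CDR3s are uniform random 20-mers, which sit
far from any reference with overwhelming probability. The default
scenarios cover the regimes that matter: well separated components
(2000 donor / 500 control cells, signal fraction 0.3, noise NB(2, 0.7)
with mean ≈ 0.86, signal NB(20, 0.2) with mean 80), a low-signal sample
(signal fraction 0.07), a sample with zero controls, and a small sample
(200 donor cells, below the ~300-cell stability floor). Acceptance-style
checks use 20 seeded replicates at 2000 cells and bootstrap sizes
{100, 2000} at 15 iterations — sizes at which every quantity of interest
is already stable.

What the generator does *not* emulate: sequencing-read noise, doublets,
per-cell depth variation, antigen-specific noise shapes, or clonal
structure in the CDR3s. Passing tests therefore demonstrate that the
estimator recovers the model's own generating process and that the
pipeline's contracts hold — not that real data follow an NB mixture; that
judgment rests on the model-comparison tooling applied to each real
sample.

## Numerical choices

- NB log-PMF via log-gamma directly; PMFs only as exp(log-PMF).
- Optimizer: Nelder–Mead, NLL tolerance 10⁻⁸, 500 iterations for single
  fits and 2000 for 5-parameter mixtures (all configurable). Parameters
  are clipped inside the objective (n ∈ [10⁻⁹, 10⁹], p and ω bounded away
  from {0, 1}) so wandering simplex vertices cannot produce NaNs.
- Degenerate inputs: zero-variance count vectors raise a
  `DegenerateDataError` for single fits; mixture initialization falls back
  to method-of-moments estimates of the full data (near-Poisson fallback
  n = 100 when the data are not overdispersed) with a logged warning.
- All randomness flows through explicit `numpy.random.Generator` seeds; no
  global state. Reruns with the same seed are byte-identical.

## Limitations

Two components only (a third "intermediate" population would be absorbed
into whichever component is closer); no EM — direct NLL minimization can
in principle stop at a local optimum, mitigated by the data-driven
initializations; no per-cell covariates (e.g. total UMI depth); and the
posterior is per-count, so two cells with the same count always get the
same probability.
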