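# Methods

## The phenology model

The response is whether a single brood observation indicates a certainly
fledged brood. Atlas codes are encoded as 13 → 1; 9, 15, 16, 18, 19 → 0;
every other code is excluded with a per-code count (real extracts contain
many codes outside this mapping, so exclusion is bookkeeping, not an
error). Code 16 ("adult with food for nestlings") is deliberately in the
0-class even though post-fledging feeding occurs; the model therefore
estimates the date at which *reports* flip to "certainly fledged", which
is slightly conservative relative to true fledging.

With day of year and elevation z-transformed (sample mean/SD, ddof = 1),

    y_i ~ Bernoulli(p_i)
    logit(p_i) = β0 + β1·e_i + (β2 + β3·e_i)·(t_i + d_year[i])
    d_year ~ Normal(0, σ)

The displacement enters the *date axis*, so a year's entire seasonal curve
slides; the date slope β2 and its elevational modulation β3 are shared
across years. A positive β3 lets the rise steepen with elevation (shorter
seasons higher up). The 50%-fledged date is the root of the linear
predictor, `t50_z(e) = −(β0+β1 e)/(β2+β3 e) − d`; it is evaluated per
posterior draw and back-transformed, never clamped to the calendar — a
weakly identified species legitimately produces intervals far outside
[1, 366], and propagating that is part of the method. A draw with an
exactly zero denominator yields a non-finite t50; non-finite draws are
excluded from summaries only when they are ≤1% of all draws (count always
reported), otherwise they propagate into the extreme quantiles untrimmed.

Model assumptions worth stating: observations are independent given
(date, elevation, year); observer effort may vary with date and elevation
but detection probability of a given breeding stage does not vary with
elevation; the seasonal rise is logistic on the logit scale; year effects
are exchangeable Normal shifts. Detection-probability modelling and
multi-brood mixtures (relevant for thrushes) are explicitly out of scope.

### Priors and sampling

Priors: Normal(0, 5) on each β (weakly informative on z-scale covariates),
half-Normal(0, 2) on σ (z-date units; 2 z-units ≈ 70 days of between-year
SD, far beyond anything plausible). Both are configurable.

The posterior is sampled with an in-package Hamiltonian Monte Carlo
sampler: leapfrog integration, dual-averaging step-size adaptation tuned to an
average Metropolis acceptance rate of 0.8, one diagonal mass-matrix window
in the middle of warmup, jittered trajectory lengths (λ ≈ 1.2, ≤64 steps), and a
non-centered parameterization d = σ·u, u ~ N(0,1), with σ sampled on the
log scale (Jacobian included). Chains start from a maximum-likelihood GLM
fit of the non-hierarchical model plus jitter. Default protocol: 4 chains
× 2000 transitions, first halves used for adaptation and discarded, so
exactly 4000 draws are retained. Rank-normalized split R-hat and bulk/tail
ESS are computed with ArviZ; max R-hat > 1.05 sets a non-convergence flag
and raises a warning (never silent). On the default synthetic preset the
sampler reaches R-hat ≤ 1.01 with bulk ESS ≥ 600 in roughly two seconds on
one CPU; energy divergences are counted and reported in the fit config
echo.

Point summaries are posterior means by default (medians by option);
intervals are 2.5/97.5% quantiles. Tables are reported for 1650/1850/2050 m
(presentation elevations), per-year deviations at the 1743 m mean
elevation, and delays as both total days and days per 100 m.

## Synthetic observation generator

The generator is the exact forward model above. Truth can be specified
directly as z-scale βs or constructed from natural units: t50 at a
reference elevation, delay in days/100 m (β3 = 0 under this construction),
a logit slope per day (default 0.15/day, spreading the 10–90% transition
over ≈29 days), and a between-year SD in days. Effort is uniform over
May 1–Aug 31 (doy 121–243) and 1500–2200 m by default, with an optional
linear late-season up-weighting to mimic effort growing over the season;
class-0 Atlas codes are drawn with weights 4:5:853:72:26 (codes
9/15/16/18/19), matching the observed code frequencies of the study
system, and class 1 always maps to code 13.

The default "coal-tit-like" preset fixes the study conditions used in
tests and the acceptance script: n = 764 observations, 10 years
(2013–2022), t50(1650 m) = 165.0, delay 1.5 days/100 m, between-year SD
2 days. Under these conditions the t50(1650) point estimate from one
simulated dataset is unbiased with SD ≈ 1.6 days (measured over 24
replicates), of which ≈0.6 days comes from the realized mean of the ten
year displacements; recovery checks therefore average three replicate
simulate–fit runs rather than betting on a single realization, and the
delay's 95% interval covers truth at close to its nominal rate.

What the generator does **not** emulate: spatially structured effort,
elevation-dependent detectability, repeated reports of one brood, multiple
broods per pair, and code-misassignment (e.g. 16 recorded for a fledged
brood). Passing recovery tests therefore demonstrates correctness of the
estimator under the stated model, not robustness to those real-data
features.

## Exceedance-day climatology

"Exceeded" means strictly greater than the threshold; ties are not
exceedances (they matter only on synthetic data and are pinned by tests).
The search window defaults to doy 1–212 (Jan 1–Jul 31) as the reading of
"spring or early summer"; a January warm spell can therefore register for
low thresholds, which is documented behaviour, and the window is
configurable. Bands are all cells within ±100 m of the 1500 m and 2200 m
centres. Cells whose series never exceeds the threshold in the window are
excluded from the band median; if more than half of a band's cells are
missing, that band median is undefined for that year/threshold and the
year is dropped (with a logged count) from the median across years. The
median of an even number of values is the mean of the two central values.
The decadal trend is the OLS slope of the yearly difference on year × 10,
reported only with ≥3 usable years. The year span is configurable (the
source products cover 1991–2022).

The synthetic grid is `mean_ref − lapse·(elev−ref)/100 +
A·cos(2π(doy−phase)/365.25)` plus stationary AR(1) noise. Defaults: 8 °C
annual mean at 1500 m, amplitude 9 °C, phase doy 200 (seasonal peak in
late July), lapse 0.65 °C/100 m (standard atmosphere), noise SD 3 °C with
lag-1 autocorrelation 0.7 — round numbers consistent with Alpine daily
series; ten cells populate the two bands. A property worth knowing: for a
sinusoidal cycle the band lag is *not* monotone in threshold over the full
sweep — it is U-shaped, decreasing while crossings move toward the
maximum-slope day and increasing beyond it — so monotonicity is only
asserted for thresholds above every cell's annual mean.

## Budburst trend

OLS of budburst day of year on elevation and year, both continuous, via
statsmodels. Year is centered at its sample mean by default (the
uncentered intercept is also reported; predictions and delays are
invariant). Standardized coefficients are raw coefficients × covariate SD.
The 1500→2200 m delay multiplies the elevation coefficient by the 700 m
span — an intentional extrapolation, since stations end at 1933 m.
Generator defaults: 41 stations uniform over 1000–1933 m, elevation
coefficient 0.0274 days/m (2.74 days/100 m), year coefficient −0.14
days/yr, Gaussian noise SD 5 days, giving budburst near day 150 at 1500 m
mid-study.

## Numerical choices and problem sizes

* Bernoulli log likelihood via `y·η − logaddexp(0, η)`: finite out to
  |η| ≈ 700.
* Raw binned proportions use the Beta(k+1, n−k+1) uniform-prior posterior
  quantiles (Jeffreys by option). At k = 0 or k = n the interval
  deliberately sits off the degenerate point estimate (e.g. k=0, n=5 →
  lower bound 0.0042); bins are right-open 20-day intervals over three
  elevational belts (1500–1733, 1734–1967, 1968–2200 m) and empty bins are
  emitted with n = 0.
* Elevation/year filters are closed intervals; day of year follows the
  real calendar (leap years reach 366), with no 365-day normalization.
* Interval-calibration checks run 25 simulate–fit repetitions at reduced
  chain length (4 × 500) with a ≥21/25 acceptance band (the two-sided
  2.5% tail of Binomial(25, 0.95)); budburst coverage uses 200 OLS
  repetitions with a 183–197 band (Binomial(200, 0.95), 99% two-sided).
  These sizes keep the full test suite under about a minute while leaving
  the bands statistically meaningful.

## Known limitations

* The HMC sampler uses a fixed trajectory-length heuristic rather than
  NUTS; for much larger hierarchies (many more years or crossed random
  effects) its efficiency would degrade before its correctness.
* One model per species; no pooling across species, no spatial effects,
  no fixed categorical year term (the random displacement subsumes it on
  the date axis).
* σ is weakly identified with very few years; single-year fits complete
  but return a prior-dominated σ, and the convergence flag should be
  heeded.
* The exceedance analysis assumes a contiguous daily series per cell-year
  and performs no interpolation or reprojection of native grid formats.
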