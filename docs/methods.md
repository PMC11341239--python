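# Methods

## The model

The Lomax-tangent construction turns a baseline distribution function
G(x; ξ) on (0, ∞) into a new lifetime distribution by the
transformed–transformer recipe: with generator density
r(t) = (k/s)(1 + t/s)^(−k−1) (Lomax with scale s and shape k, support
t > 0) and link W(G) = tan(πG/2),

    F(x) = ∫₀^{tan(πG(x)/2)} r(t) dt = 1 − (1 + tan(πG(x)/2)/s)^(−k).

Differentiating gives the density

    f(x) = (πk/2s) g(x) sec²(πG(x)/2) (1 + tan(πG(x)/2)/s)^(−k−1),

the hazard replaces the last exponent by −1 (h = f/(1−F); the package
computes h from that identity, so the two forms agree by construction),
and inverting F gives the closed-form quantile

    Q(u) = G⁻¹( (2/π) arctan( s ((1−u)^(−1/k) − 1) ) ),

which makes inverse-transform sampling exact — no rejection step is
needed or used.

Interpretation of the parameters: the link maps the baseline's
probability scale onto (0, ∞) and the Lomax generator reweights it.
Small k fattens the upper tail (for thin-tailed baselines the survival
behaves like (πs(1−G(x))/2)^k, i.e. the baseline's log-survival is
multiplied by k), while s shifts where the reweighting bites. Depending
on the baseline this produces increasing, decreasing, unimodal, bathtub
and bimodal density/hazard shapes; the Rayleigh sub-model in particular
admits a genuinely bimodal density (e.g. s=0.5, k=0.3, β=1).

Baselines are frozen to the parameterizations the named sub-models are
defined under: Weibull G = 1 − e^(−(x/a)^b) (a scale, b shape), gamma in
the one-parameter unit-scale form G = γ(β, x)/Γ(β) (an optional scale θ,
default 1, is provided as an extension), Rayleigh G = 1 − e^(−βx²), and
exponential G = 1 − e^(−βx). Fitted results are only comparable across
software under these exact conventions.

## Numerical design

**Upper tail.** tan(πG/2) overflows as G → 1. All family functions
evaluate the link through the baseline survival: for G > 1/2,
tan(πG/2) = 1/tan(π(1−G)/2) with 1 − G computed directly by the
baseline's survival function, and log cos(πG/2) = log sin(π(1−G)/2).
Survival and log-density use log1p throughout, so log F̄ is finite and
monotone even at G = 1 − 10⁻¹⁵. The quantile function likewise switches
branches: for s((1−u)^(−1/k) − 1) > 1 it computes the baseline survival
level (2/π)·arctan(1/·) and inverts the baseline's survival function
(each baseline ships an analytic inverse survival), which keeps extreme
quantiles accurate where arctan would saturate in double precision.

**Support edges.** The cdf clamps to exact 0/1 outside the support and
the density evaluates to its limiting value at the lower edge (so the
exponential baseline has g(0) = β, the Weibull b < 1 case diverges there,
etc.). Out-of-support log-density is −∞ by convention rather than an
exception; the likelihood reports −∞ totals as an invalid parameter
region to the optimizer, while the model constructor rejects data at or
below the support bound outright, listing the offending indices.

## Estimation

The sample log-likelihood is the sum of the family log-density,

    ℓ = n log k + n log π − n log s − n log 2 + Σ log g(xᵢ; ξ)
        + Σ log sec²(πG(xᵢ)/2) − (k+1) Σ log(1 + tan(πG(xᵢ)/2)/s).

Gradients and Hessians are numeric (central differences via statsmodels'
differentiation tools); analytic score expressions are deliberately not
used — the numeric gradient of a verified log-likelihood is the safer
contract, and the unit tests pin the likelihood itself against
finite-difference and published-value oracles.

**Multi-start policy.** The (s, k) pair is weakly identified: as
s, k → ∞ with s/k fixed the Lomax generator converges to an exponential
generator, so the family contains a limiting sub-family on the boundary
of its parameter space and the profile likelihood in (s, k) has a long,
nearly flat ridge. Optimization therefore runs Nelder–Mead in
log-parameter space from multiple starts (default 20: five heuristic
moment-flavoured starts plus Latin-hypercube draws over data-driven
log-ranges, seeded and hence reproducible) and keeps the best endpoint.

**Standard errors and the convergence criterion.** Standard errors come
from the observed information (negative numeric Hessian at the MLE);
expected information is not available without analytic integrals. For
some samples — especially small n under heavy-tailed truths — the
likelihood supremum is attained only in the s, k → ∞ limit. Such
endpoints are detectable: the observed information becomes numerically
singular (condition number ≥ 10¹⁴, often with negative eigenvalues,
versus ≤ ~10⁹ at regular interior optima). A fit is flagged
`cov_reliable` only when the information matrix is positive definite
with condition number below 10¹²; the threshold sits in the middle of a
five-orders-of-magnitude gap between the two regimes, so its exact value
is immaterial. When the information is merely near-singular the
covariance falls back to a pseudo-inverse.

## Goodness of fit

Information criteria from the maximized log-likelihood ℓ̂ with p
parameters and n observations: AIC = −2ℓ̂ + 2p, BIC = −2ℓ̂ + p log n,
HQIC = −2ℓ̂ + 2p log log n, and CAIC is the small-sample corrected AIC,
AIC + 2p(p+1)/(n−p−1). Reports label the likelihood column −ℓ̂.

W* and A* follow the Chen–Balakrishnan recipe for composite hypotheses:
u₍ᵢ₎ = F̂(x₍ᵢ₎) are converted to normal scores y = Φ⁻¹(u), standardized,
mapped back through Φ, and the modified statistics

    W* = [Σ(vᵢ − (2i−1)/2n)² + 1/12n](1 + 0.5/n)
    A* = [−n − (1/n)Σ(2i−1)(ln vᵢ + ln(1 − v₍ₙ₊₁₋ᵢ₎))](1 + 0.75/n + 2.25/n²)

are applied to the transformed values. `method="classical"` applies the
same formulas to the u₍ᵢ₎ directly (this equals scipy's Cramér–von Mises
statistic up to the small-sample factor). The default was chosen because
it is what the cited recipe actually prescribes and is standard in the
distribution-fitting literature.

K-S p-values use the parameters-known asymptotic Kolmogorov distribution
by default; since parameters are estimated this is approximate (usually
conservative in the sense of overstating p), and a parametric-bootstrap
alternative is available via `n_boot`.

## Series machinery

The cdf admits the formal exp-G expansion
F = Σᵢ Σⱼ Wᵢⱼ G^(2j+i) with Wᵢⱼ = −C(−k, i) s^(−i) bⱼ⁽ⁱ⁾ (π/2)^(2j+i),
where bⱼ⁽ⁱ⁾ is the z^(2j+i) coefficient of tan(z)^i, computed exactly as
rationals by formal division of the sine by the cosine series and
repeated convolution (b₀⁽ⁱ⁾ = 1, b₁⁽ⁱ⁾ = i/3, b₂⁽ⁱ⁾ = i(5i+7)/90).
Weights are assembled in log-magnitude/sign form to survive extreme k or
deep truncation. The expansion is a cross-check, not a production path:
the inner tangent series requires πG/2 < π/2 and the outer binomial
series requires tan(πG/2) < s, so agreement with the closed form is
validated on the region where both hold (error < 10⁻⁶ at truncation
30–60 for the tested parameter sets, improving monotonically with
truncation) and the closed forms are used everywhere else. The mgf's
series form inherits the same restriction — the integral over the upper
tail always leaves the convergence region — so its cross-check compares
the partial (region-restricted) mgf integral only.

Order statistics use the exact finite form
f₍ᵢ:ₙ₎ = [n!/((i−1)!(n−i)!)] f F^(i−1) (1−F)^(n−i) in log space; the
equivalent infinite exp-G rearrangement is not used computationally.

## Moments and shape analysis

Raw moments are quadrature integrals on the quantile scale,
μ′ᵣ = ∫₀¹ Q(u)^r du, with the integration split near u = 1; the exp-G
moment series is not used (limited convergence region). Skewness uses
the standard moment-ratio formula and kurtosis is reported in the
non-excess (β₂) convention, with the excess value exposed alongside.
Divergent integrals raise an explicit moment-nonexistence error rather
than returning NaN. Critical points of log f and log h are located by
sign-scanning their analytic derivatives (assembled from the baseline's
closed-form g′/g) on a grid over the central 99.98% quantile range
(configurable) and refined by Brent's method; each root is labeled
max/min by the local curvature.

## Data sets and descriptive statistics

The two packaged samples (72 Wheaton River flood-peak exceedances; 63
glass-fibre strengths) are embedded as literal tuples, guarded by
checksums re-keyed independently from the source listing. `describe`
uses biased (divide-by-n) sample moments; both kurtosis conventions are
printed because published summaries of these classic data sets are
inconsistent about the convention.

## Monte Carlo study

`run_simulation` draws n variates by inverse transform, refits by ML,
and summarizes bias B, mean squared error M, Wald coverage C and average
interval width AvW per parameter and sample size. Defaults follow the
study design the family was published with: sample sizes
(50, 100, 300, 500) and 1000 replications; the confidence level is 0.95
(conventional; it is not stated in the source design). Replicate seeds
are spawned from the master seed with `SeedSequence`, so every cell is
independently reproducible. Replicates without a regular interior
optimum (the s, k ridge, above) are excluded and counted; a cell with
more than 20% exclusions is flagged unreliable and rendered as NA.
Cell-level numeric agreement with any particular published run is not
expected — on a flat ridge the endpoint depends on optimizer details —
but the qualitative behaviour (bias and MSE shrink as n grows, coverage
approaches the nominal level) is reproduced and asserted. The bundled
acceptance study runs a reduced design (200 replications, n ∈ {50, 500},
6 starts per fit) chosen to keep a full run in minutes on one CPU.

## What the synthetic data does and does not show

Simulated samples are i.i.d. draws from the family itself via the exact
quantile transform. They exercise estimator behaviour under correct
specification only: no censoring, ties, measurement rounding,
covariates, or model misspecification. Passing recovery and coverage
tests therefore says the estimation machinery is correct, not that the
family fits any particular real phenomenon; the two packaged real data
sets carry that burden.

## Known limitations

- No censored or truncated likelihood contributions.
- The (s, k) ridge means individual generator-parameter estimates can be
  unstable even when the fitted distribution (and hence likelihood, GOF,
  quantiles) is stable; compare fits by likelihood and GOF, not by
  (s, k) values.
- K-S/W*/A* p-values do not account for parameter estimation unless the
  bootstrap option is used.
- The gamma baseline's numeric quantile inversion (scipy's incomplete
  gamma inverse) is the only non-closed-form inversion; it is accurate
  but slower than the other baselines.
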