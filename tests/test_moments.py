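"""Moments, mgf and shape analysis."""

import numpy as np
import pytest
from scipy.integrate import quad

from lomaxtan import LomaxTangent
from lomaxtan.series import expg_weights
from lomaxtan.moments import (
    MomentError,
    density_critical_points,
    hazard_critical_points,
    mgf,
    moment_set,
    pwm,
    raw_moment,
    skewness_kurtosis,
)

LT_W_2221 = LomaxTangent("weibull", s=2.0, k=2.0, xi=(1.0, 2.0))


def test_zeroth_moment_is_one(lt_exp_unit):
    assert raw_moment(lt_exp_unit, 0) == 1.0


def test_first_moment_matches_monte_carlo(lt_exp_unit):
    m1 = raw_moment(lt_exp_unit, 1)
    sample = lt_exp_unit.rvs(1_000_000, seed=5)
    se = sample.std(ddof=1) / np.sqrt(sample.size)
    assert abs(m1 - sample.mean()) < 4 * se


def test_quantile_scale_agrees_with_x_scale_quadrature():
    """mu'_r from int Q(u)^r du equals int x^r f(x) dx (independent scheme)."""
    d = LT_W_2221
    for r in (1, 2):
        u_scale = raw_moment(d, r)
        x_scale, _ = quad(lambda x: x**r * d.pdf(x), 0.0, d.ppf(1 - 1e-14), limit=300)
        assert abs(u_scale - x_scale) < 1e-6


def test_pwm_weighted_by_baseline_cdf():
    """tau_{r,0} reduces to the plain raw moment; tau_{0,1} = E[G(X)]."""
    d = LT_W_2221
    assert pwm(d, 1, 0) == pytest.approx(raw_moment(d, 1), abs=1e-8)
    eg, _ = quad(lambda x: d.baseline.cdf(x, *d.params.xi) * d.pdf(x), 0, d.ppf(1 - 1e-13), limit=300)
    assert pwm(d, 0, 1) == pytest.approx(eg, abs=1e-6)


def test_moment_ratio_formula_symmetric_case():
    """The skewness formula vanishes for symmetric raw moments (uniform on (0, 2))."""
    m1, m2, m3 = 1.0, 4.0 / 3.0, 2.0  # raw moments of U(0,2)
    skew = (m3 - 3 * m2 * m1 + 2 * m1**3) / (m2 - m1 * m1) ** 1.5
    assert skew == pytest.approx(0.0, abs=1e-12)


def test_skewness_kurtosis_match_simulation():
    d = LT_W_2221
    skew, kurt = skewness_kurtosis(d)
    x = d.rvs(1_000_000, seed=9)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    skew_mc = np.mean((x - m) ** 3) / m2**1.5
    kurt_mc = np.mean((x - m) ** 4) / m2**2
    assert abs(skew - skew_mc) < 0.02
    assert abs(kurt - kurt_mc) < 0.1


def test_pearson_inequality_on_shape_grid():
    """kurtosis >= skewness^2 + 1 and all values finite over a (a, b) surface."""
    for a in (0.5, 1.0, 2.0):
        for b in (0.8, 1.5, 3.0):
            d = LomaxTangent("weibull", s=1.5, k=1.2, xi=(a, b))
            skew, kurt = skewness_kurtosis(d)
            assert np.isfinite(skew) and np.isfinite(kurt)
            assert kurt >= skew**2 + 1 - 1e-9


def test_mgf_at_zero_and_derivatives(lt_exp_unit):
    assert mgf(lt_exp_unit, 0.0) == 1.0
    h = 1e-4
    d1 = (mgf(lt_exp_unit, h) - mgf(lt_exp_unit, -h)) / (2 * h)
    assert d1 == pytest.approx(raw_moment(lt_exp_unit, 1), abs=1e-6)
    d2 = (mgf(lt_exp_unit, h) - 2.0 + mgf(lt_exp_unit, -h)) / h**2
    assert d2 == pytest.approx(raw_moment(lt_exp_unit, 2), abs=1e-5)


def test_mgf_series_cross_check_on_convergence_region():
    """Exp-G series reproduces the partial mgf integral where the expansion converges."""
    d = LomaxTangent("exponential", s=3.0, k=2.0, xi=(1.0,))
    t = 0.2
    g_end = 0.6
    x_end = d.baseline.ppf(g_end, 1.0)
    target, _ = quad(lambda x: np.exp(t * x) * d.pdf(x), 0.0, x_end, limit=200)
    total = 0.0
    for term in expg_weights(d.params, 40, 40):
        val, _ = quad(
            lambda v: np.exp(t * d.baseline.ppf(v, 1.0)) * v ** (term.power - 1),
            0.0, g_end, limit=100,
        )
        total += term.weight * term.power * val
    assert total == pytest.approx(target, abs=1e-4)


def test_mgf_divergence_signalled(lt_exp_unit):
    # upper tail decays like exp(-k beta x); t far above that rate cannot converge
    with pytest.raises(MomentError):
        mgf(lt_exp_unit, 50.0)


def test_moment_set_consistency(lt_exp_unit):
    ms = moment_set(lt_exp_unit)
    assert ms.variance >= 0
    assert ms.excess_kurtosis == pytest.approx(ms.kurtosis - 3.0)
    assert ms.mean == pytest.approx(raw_moment(lt_exp_unit, 1), abs=1e-9)


# -- critical points -------------------------------------------------------

def test_rayleigh_sub_model_bimodal():
    """The Rayleigh sub-model admits a bimodal density: two maxima separated by a minimum."""
    d = LomaxTangent("rayleigh", s=0.5, k=0.3, xi=(1.0,))
    pts = density_critical_points(d)
    kinds = [p.kind for p in pts]
    assert kinds.count("max") == 2 and kinds.count("min") == 1
    # grid-scan oracle: count local maxima of the pdf directly
    xs = np.linspace(1e-3, d.ppf(1 - 1e-4), 4000)
    f = d.pdf(xs)
    n_max = int(np.sum((f[1:-1] > f[:-2]) & (f[1:-1] > f[2:])))
    assert n_max == 2


def test_monotone_density_has_no_critical_points():
    d = LomaxTangent("exponential", s=1.0, k=0.5, xi=(1.0,))
    assert density_critical_points(d) == []


def test_critical_points_are_roots_with_correct_curvature():
    d = LomaxTangent("weibull", s=2.0, k=2.0, xi=(1.0, 2.0))
    pts = density_critical_points(d)
    assert pts, "expected a unimodal maximum"
    for p in pts:
        h = 1e-5 * max(1.0, abs(p.x))
        dlogf = (np.log(d.pdf(p.x + h)) - np.log(d.pdf(p.x - h))) / (2 * h)
        assert abs(dlogf) < 1e-6
        lam = (np.log(d.pdf(p.x + h)) - 2 * np.log(d.pdf(p.x)) + np.log(d.pdf(p.x - h))) / h**2
        assert (lam < 0) == (p.kind == "max")


def test_sign_pattern_matches_empirical_monotonicity():
    d = LomaxTangent("rayleigh", s=0.5, k=0.3, xi=(1.0,))
    pts = sorted(p.x for p in density_critical_points(d))
    edges = [1e-3] + pts + [d.ppf(1 - 1e-4)]
    for lo, hi in zip(edges[:-1], edges[1:]):
        xs = np.linspace(lo + 1e-4, hi - 1e-4, 200)
        diffs = np.diff(d.pdf(xs))
        assert np.all(diffs > 0) or np.all(diffs < 0)


def test_hazard_critical_points_bathtub_and_increasing():
    # glass-fibre-like LT-W: steeply increasing hazard, no interior stationary point
    d_inc = LomaxTangent("weibull", s=7.522, k=0.755, xi=(1.1863, 3.8308))
    assert hazard_critical_points(d_inc, bracket=(0.05, 2.0)) == []
    # Wheaton-like LT-W: hazard rises then falls (upside-down bathtub): one max
    d_ubt = LomaxTangent("weibull", s=0.0669, k=0.1927, xi=(7.0293, 1.5858))
    pts = hazard_critical_points(d_ubt)
    assert [p.kind for p in pts].count("max") >= 1
    # cross-check each root against a finite-difference log-hazard slope
    for p in pts:
        h = 1e-5 * max(1.0, abs(p.x))
        slope = (np.log(d_ubt.hazard(p.x + h)) - np.log(d_ubt.hazard(p.x - h))) / (2 * h)
        assert abs(slope) < 1e-6
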