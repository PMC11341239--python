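"""Exp-G series machinery and order statistics.

The family cdf admits the formal double expansion

    F(x) = sum_{i>=1} sum_{j>=0} W_{i,j} [G(x)]^{2j+i},
    W_{i,j} = -C(-k, i) s^{-i} b_j^{(i)} (pi/2)^{2j+i},

where ``b_j^{(i)}`` is the coefficient of ``z^{2j+i}`` in the Maclaurin
series of ``tan(z)^i`` (``b_0^{(i)} = 1``, ``b_1^{(i)} = i/3``,
``b_2^{(i)} = i(5i+7)/90``) and ``C(-k, i)`` the generalized binomial
coefficient.  Each term is the cdf of an exp-G distribution with power
parameter ``2j+i``, so the family is an infinite linear combination of
exp-G distributions.

The tangent series has radius of convergence ``pi/2``; the composed
expansion is validated against the closed form on ``G(x) <~ 0.7`` and is a
cross-check only — the closed forms in :mod:`lomaxtan.family` are the
production path everywhere.

Coefficients ``b_j^{(i)}`` are exact rationals, obtained by formally
dividing the sine by the cosine series and raising to the i-th power with
:class:`fractions.Fraction` arithmetic.

Order statistics use the exact finite form

    f_{i:n}(x) = n!/((i-1)!(n-i)!) f(x) F(x)^{i-1} (1-F(x))^{n-i},

in log space via ``betaln``; the equivalent alternating-binomial form is
``sum_p (-1)^p C(n-i, p) f F^{p+i-1}`` times the same constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy import special

from .baselines import DomainError
from .family import LomaxTangent, LTGParams

__all__ = [
    "tan_power_coeff",
    "ExpGTerm",
    "expg_weights",
    "cdf_series",
    "pdf_series",
    "order_stat_pdf",
]

_MAX_ORDER = 600  # highest power of z retained in formal series work


@lru_cache(maxsize=None)
def _tan_series(n_terms: int) -> tuple[Fraction, ...]:
    """Odd-order Maclaurin coefficients of tan z: tan z = sum_m c_m z^{2m+1}."""
    if n_terms > _MAX_ORDER:
        raise DomainError(f"series truncation depth {n_terms} exceeds limit {_MAX_ORDER}")
    # sin z = sum (-1)^m z^{2m+1}/(2m+1)!,  cos z = sum (-1)^m z^{2m}/(2m)!
    sin_c = [Fraction((-1) ** m, _factorial(2 * m + 1)) for m in range(n_terms)]
    cos_c = [Fraction((-1) ** m, _factorial(2 * m)) for m in range(n_terms)]
    # formal division tan = sin / cos on the z^{2m+1} grid
    tan_c: list[Fraction] = []
    for m in range(n_terms):
        acc = sin_c[m]
        for r in range(m):
            acc -= tan_c[r] * cos_c[m - r]
        tan_c.append(acc)
    return tuple(tan_c)


@lru_cache(maxsize=None)
def _factorial(n: int) -> int:
    out = 1
    for v in range(2, n + 1):
        out *= v
    return out


@lru_cache(maxsize=None)
def _tan_power_series(i: int, n_terms: int) -> tuple[Fraction, ...]:
    """Coefficients d_j with tan(z)^i = sum_j d_j z^{2j+i} (exact rationals)."""
    base = _tan_series(n_terms)
    power = list(base)
    for _ in range(i - 1):
        power = _convolve_truncated(power, base, n_terms)
    return tuple(power)


def _convolve_truncated(a, b, n_terms):
    # a holds coefficients of z^{2p+m}, b of z^{2q+1}; the product's
    # coefficient of z^{2j+(m+1)} is sum over p+q=j
    out = [Fraction(0)] * n_terms
    for p, ap in enumerate(a[:n_terms]):
        for q, bq in enumerate(b):
            if p + q >= n_terms:
                break
            out[p + q] += ap * bq
    return out


def tan_power_coeff(i: int, j: int, *, exact: bool = False):
    """Coefficient ``b_j^{(i)}`` of ``z^{2j+i}`` in ``tan(z)^i``.

    ``b_0^{(i)} = 1``, ``b_1^{(i)} = i/3``, ``b_2^{(i)} = i(5i+7)/90``.
    With ``exact=True`` the value is returned as a :class:`~fractions.Fraction`.
    """
    if i < 1 or j < 0:
        raise DomainError("need i >= 1 and j >= 0")
    coeffs = _tan_power_series(int(i), int(j) + 1)
    val = coeffs[j]
    return val if exact else float(val)


@dataclass(frozen=True)
class ExpGTerm:
    """One exp-G mixture term: weight W_{i,j} attached to power 2j+i."""

    i: int
    j: int
    power: int
    weight: float


def _gen_binom_neg_k(k: float, i_max: int) -> np.ndarray:
    """C(-k, i) for i = 1..i_max by the product recurrence (floats)."""
    out = np.empty(i_max)
    val = 1.0
    for i in range(1, i_max + 1):
        val *= (-k - (i - 1)) / i
        out[i - 1] = val
    return out


def expg_weights(params: LTGParams, i_max: int = 20, j_max: int = 20) -> list[ExpGTerm]:
    """Truncated exp-G expansion weights ``W_{i,j} = -C(-k,i) s^{-i} b_j^{(i)} (pi/2)^{2j+i}``."""
    if i_max < 1 or j_max < 1:
        raise DomainError("truncation bounds must be >= 1")
    s, k = params.s, params.k
    binom = _gen_binom_neg_k(k, i_max)
    terms = []
    log_half_pi = np.log(np.pi / 2.0)
    for i in range(1, i_max + 1):
        coeffs = _tan_power_series(i, j_max + 1)
        prefactor = -binom[i - 1]
        for j in range(j_max + 1):
            power = 2 * j + i
            b = coeffs[j]
            # log-magnitude assembly guards overflow at extreme k or deep truncation
            log_mag = (
                np.log(abs(prefactor)) if prefactor != 0 else -np.inf
            ) - i * np.log(s) + power * log_half_pi + _log_abs_fraction(b)
            sign = np.sign(prefactor) * (1 if b >= 0 else -1)
            terms.append(ExpGTerm(i, j, power, float(sign * np.exp(log_mag))))
    return terms


def _log_abs_fraction(fr: Fraction) -> float:
    if fr == 0:
        return -np.inf
    import math

    return math.log(abs(fr.numerator)) - math.log(fr.denominator)


def cdf_series(dist: LomaxTangent, x, i_max: int = 20, j_max: int = 20):
    """Truncated exp-G series approximation to the family cdf (cross-check path)."""
    terms = expg_weights(dist.params, i_max, j_max)
    G = np.asarray(dist.baseline.cdf(x, *dist.params.xi), dtype=float)
    out = np.zeros_like(G)
    for t in terms:
        out += t.weight * G**t.power
    return out if out.ndim else float(out)


def pdf_series(dist: LomaxTangent, x, i_max: int = 20, j_max: int = 20):
    """Term-wise derivative of :func:`cdf_series`: mixture of exp-G densities."""
    terms = expg_weights(dist.params, i_max, j_max)
    G = np.asarray(dist.baseline.cdf(x, *dist.params.xi), dtype=float)
    g = np.asarray(dist.baseline.pdf(x, *dist.params.xi), dtype=float)
    out = np.zeros_like(G)
    for t in terms:
        out += t.weight * t.power * G ** (t.power - 1)
    out *= g
    return out if out.ndim else float(out)


def order_stat_pdf(dist: LomaxTangent, n: int, i: int, x):
    """Density of the i-th order statistic of an i.i.d. LT-G sample of size n."""
    n, i = int(n), int(i)
    if not 1 <= i <= n:
        raise DomainError(f"rank i must lie in [1, {n}], got {i}")
    logf = np.asarray(dist.logpdf(x), dtype=float)
    logF = np.log(np.clip(dist.cdf(x), 1e-300, 1.0))
    logS = np.asarray(dist.logsf(x), dtype=float)
    logconst = -special.betaln(i, n - i + 1)  # log n!/((i-1)!(n-i)!)
    with np.errstate(invalid="ignore"):
        out = np.exp(logconst + logf + (i - 1) * logF + (n - i) * logS)
    out = np.where(np.isfinite(out), out, 0.0)
    return out if np.ndim(out) else float(out)
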