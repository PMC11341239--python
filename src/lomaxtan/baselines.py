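"""Baseline distributions that the Lomax-tangent generator is composed with.

A :class:`Baseline` supplies the cdf ``G``, pdf ``g``, survival ``1-G``,
quantile ``G^{-1}`` and the logarithmic derivative ``g'/g`` of a positive
continuous distribution.  Four baselines are shipped, frozen to the
parameterizations under which the family's named sub-models (LT-W, LT-Ga,
LT-R, LT-E) are defined:

========== ============================ =======================
name       cdf G(x)                     parameters
========== ============================ =======================
weibull    1 - exp(-(x/a)^b)            a (scale), b (shape)
gamma      gammainc(beta, x/theta)      beta (shape), theta=1
rayleigh   1 - exp(-beta x^2)           beta
exponential 1 - exp(-beta x)            beta (rate)
========== ============================ =======================

The gamma baseline is the one-parameter (unit-scale) form; an optional
scale ``theta`` is accepted as an extension and defaults to 1.

Outside the support the cdf clamps to exact 0/1 and the pdf to 0, so the
family functions built on top are total on the real line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special


class DomainError(ValueError):
    """Raised when a parameter or argument is outside its admissible domain."""


def _check_positive(params, names):
    for value, name in zip(params, names):
        if not np.all(np.isfinite(value)) or np.any(np.asarray(value) <= 0):
            raise DomainError(f"baseline parameter {name!r} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class Baseline:
    """Contract for a baseline distribution G on an interval support.

    The callables receive ``(x_or_u, *params)`` with ``x`` already clipped
    to the support by the public methods; ``_dlogpdf`` is the analytic
    derivative of ``log g`` used by the density/hazard shape analysis.
    """

    name: str
    param_names: tuple[str, ...]
    support: tuple[float, float]
    _cdf: Callable = field(repr=False)
    _sf: Callable = field(repr=False)
    _logpdf: Callable = field(repr=False)
    _ppf: Callable = field(repr=False)
    _isf: Callable = field(repr=False)
    _dlogpdf: Callable = field(repr=False)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def validate(self, params) -> tuple[float, ...]:
        params = tuple(float(p) for p in params)
        if len(params) != self.n_params:
            raise DomainError(
                f"baseline {self.name!r} takes {self.n_params} parameter(s) "
                f"{self.param_names}, got {len(params)}"
            )
        _check_positive(params, self.param_names)
        return params

    def cdf(self, x, *params):
        params = self.validate(params)
        x = np.asarray(x, dtype=float)
        lo, hi = self.support
        inside = (x > lo) & (x < hi)
        out = np.where(x <= lo, 0.0, 1.0)
        if np.any(inside):
            out = np.where(inside, self._cdf(np.clip(x, lo, hi), *params), out)
        return out if out.ndim else float(out)

    def sf(self, x, *params):
        params = self.validate(params)
        x = np.asarray(x, dtype=float)
        lo, hi = self.support
        inside = (x > lo) & (x < hi)
        out = np.where(x <= lo, 1.0, 0.0)
        if np.any(inside):
            out = np.where(inside, self._sf(np.clip(x, lo, hi), *params), out)
        return out if out.ndim else float(out)

    def logpdf(self, x, *params):
        """log g(x); -inf outside the closed support, limiting value at the lower edge."""
        params = self.validate(params)
        x = np.asarray(x, dtype=float)
        lo, hi = self.support
        inside = (x >= lo) & (x < hi)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            val = np.where(inside, self._logpdf(np.where(inside, x, lo), *params), -np.inf)
        return val if val.ndim else float(val)

    def pdf(self, x, *params):
        return np.exp(self.logpdf(x, *params))

    def ppf(self, u, *params):
        params = self.validate(params)
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u > 1) | ~np.isfinite(u)):
            raise DomainError("quantile argument must lie in [0, 1]")
        lo, hi = self.support
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            out = self._ppf(np.clip(u, 0.0, 1.0), *params)
        out = np.where(u <= 0, lo, np.where(u >= 1, hi, out))
        return out if out.ndim else float(out)

    def isf(self, q, *params):
        """Inverse survival: x with 1 - G(x) = q (accurate for tiny q)."""
        params = self.validate(params)
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1) | ~np.isfinite(q)):
            raise DomainError("inverse-survival argument must lie in [0, 1]")
        lo, hi = self.support
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            out = self._isf(np.clip(q, 0.0, 1.0), *params)
        out = np.where(q <= 0, hi, np.where(q >= 1, lo, out))
        return out if out.ndim else float(out)

    def dlogpdf(self, x, *params):
        """d/dx log g(x), defined strictly inside the support."""
        params = self.validate(params)
        x = np.asarray(x, dtype=float)
        val = self._dlogpdf(x, *params)
        return val if np.ndim(val) else float(val)


def _weibull():
    def cdf(x, a, b):
        return -np.expm1(-((x / a) ** b))

    def sf(x, a, b):
        return np.exp(-((x / a) ** b))

    def logpdf(x, a, b):
        z = (x / a) ** b
        # (b-1) log(x/a) at x=0: -inf for b>1, 0 for b=1, +inf for b<1
        term = (b - 1.0) * np.log(x / a) if b != 1.0 else np.zeros_like(np.asarray(x, dtype=float))
        return np.log(b / a) + term - z

    def ppf(u, a, b):
        return a * (-np.log1p(-u)) ** (1.0 / b)

    def isf(q, a, b):
        return a * (-np.log(q)) ** (1.0 / b)

    def dlogpdf(x, a, b):
        return (b - 1.0) / x - (b / a) * (x / a) ** (b - 1.0)

    return Baseline("weibull", ("a", "b"), (0.0, np.inf), cdf, sf, logpdf, ppf, isf, dlogpdf)


def _gamma():
    def cdf(x, beta, theta=1.0):
        return special.gammainc(beta, x / theta)

    def sf(x, beta, theta=1.0):
        return special.gammaincc(beta, x / theta)

    def logpdf(x, beta, theta=1.0):
        z = x / theta
        term = (beta - 1.0) * np.log(z) if beta != 1.0 else np.zeros_like(np.asarray(z, dtype=float))
        return term - z - special.gammaln(beta) - np.log(theta)

    def ppf(u, beta, theta=1.0):
        return theta * special.gammaincinv(beta, u)

    def isf(q, beta, theta=1.0):
        return theta * special.gammainccinv(beta, q)

    def dlogpdf(x, beta, theta=1.0):
        return (beta - 1.0) / x - 1.0 / theta

    b = Baseline("gamma", ("beta",), (0.0, np.inf), cdf, sf, logpdf, ppf, isf, dlogpdf)
    return b


def _gamma2():
    # gamma with explicit scale; extension beyond the unit-scale form
    g = _gamma()
    return Baseline("gamma2", ("beta", "theta"), (0.0, np.inf), g._cdf, g._sf, g._logpdf, g._ppf, g._isf, g._dlogpdf)


def _rayleigh():
    def cdf(x, beta):
        return -np.expm1(-beta * x * x)

    def sf(x, beta):
        return np.exp(-beta * x * x)

    def logpdf(x, beta):
        return np.log(2.0 * beta * x) - beta * x * x

    def ppf(u, beta):
        return np.sqrt(-np.log1p(-u) / beta)

    def isf(q, beta):
        return np.sqrt(-np.log(q) / beta)

    def dlogpdf(x, beta):
        return 1.0 / x - 2.0 * beta * x

    return Baseline("rayleigh", ("beta",), (0.0, np.inf), cdf, sf, logpdf, ppf, isf, dlogpdf)


def _exponential():
    def cdf(x, beta):
        return -np.expm1(-beta * x)

    def sf(x, beta):
        return np.exp(-beta * x)

    def logpdf(x, beta):
        return np.log(beta) - beta * x

    def ppf(u, beta):
        return -np.log1p(-u) / beta

    def isf(q, beta):
        return -np.log(q) / beta

    def dlogpdf(x, beta):
        return -beta + 0.0 * x

    return Baseline("exponential", ("beta",), (0.0, np.inf), cdf, sf, logpdf, ppf, isf, dlogpdf)


_REGISTRY: dict[str, Baseline] = {}


def register_baseline(baseline: Baseline) -> None:
    _REGISTRY[baseline.name] = baseline


for _b in (_weibull(), _gamma(), _gamma2(), _rayleigh(), _exponential()):
    register_baseline(_b)


def get_baseline(name: str) -> Baseline:
    """Look up a registered baseline by name (e.g. ``"weibull"``)."""
    key = name.lower().replace("-", "_")
    aliases = {
        "lt_w": "weibull", "lt_weibull": "weibull",
        "lt_ga": "gamma", "lt_gamma": "gamma",
        "lt_r": "rayleigh", "lt_rayleigh": "rayleigh",
        "lt_e": "exponential", "lt_exponential": "exponential", "exp": "exponential",
    }
    key = aliases.get(key, key)
    try:
        return _REGISTRY[key]
    except KeyError:
        raise DomainError(
            f"unknown baseline {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def available_baselines() -> list[str]:
    return sorted(_REGISTRY)
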