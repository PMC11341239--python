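"""Functional plots: density/hazard curves, fitted overlays, and TTT plots.

Matplotlib is imported lazily so the modelling core has no hard plotting
dependency.
"""

from __future__ import annotations

import numpy as np

from .family import LomaxTangent
from .gof import ttt_curve


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_pdf(dist: LomaxTangent, x=None, ax=None, **kwargs):
    ax = _axes(ax)
    if x is None:
        x = np.linspace(dist.ppf(1e-4), dist.ppf(1 - 1e-4), 400)
    ax.plot(x, dist.pdf(x), **kwargs)
    ax.set_xlabel("x")
    ax.set_ylabel("density")
    return ax


def plot_hazard(dist: LomaxTangent, x=None, ax=None, **kwargs):
    ax = _axes(ax)
    if x is None:
        x = np.linspace(dist.ppf(1e-4), dist.ppf(1 - 1e-3), 400)
    ax.plot(x, dist.hazard(x), **kwargs)
    ax.set_xlabel("x")
    ax.set_ylabel("hazard rate")
    return ax


def plot_fit(data, dist: LomaxTangent, ax=None, bins=20):
    """Histogram of the data with the fitted density overlaid."""
    ax = _axes(ax)
    data = np.asarray(data, dtype=float)
    ax.hist(data, bins=bins, density=True, alpha=0.4, edgecolor="k")
    x = np.linspace(max(1e-9, data.min() * 0.5), data.max() * 1.05, 400)
    ax.plot(x, dist.pdf(x), lw=2)
    ax.set_xlabel("x")
    ax.set_ylabel("density")
    return ax


def plot_cdf_overlay(data, dist: LomaxTangent, ax=None):
    """Empirical step cdf with the fitted cdf overlaid."""
    ax = _axes(ax)
    xs = np.sort(np.asarray(data, dtype=float))
    n = xs.size
    ax.step(xs, np.arange(1, n + 1) / n, where="post", label="empirical")
    grid = np.linspace(max(1e-9, xs.min() * 0.5), xs.max() * 1.05, 400)
    ax.plot(grid, dist.cdf(grid), label="fitted")
    ax.set_xlabel("x")
    ax.set_ylabel("F(x)")
    ax.legend()
    return ax


def plot_ttt(data, ax=None):
    """Scaled TTT transform with the exponential diagonal for reference."""
    ax = _axes(ax)
    u, t = ttt_curve(data)
    ax.plot(u, t, marker=".", ms=3)
    ax.plot([0, 1], [0, 1], ls="--", color="grey")
    ax.set_xlabel("i/n")
    ax.set_ylabel("scaled TTT")
    return ax
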