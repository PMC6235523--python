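"""Propagation of per-pathway 95% CIs to the portfolio interval.

Two combiners are provided, mirroring the two standard inventory
approaches: error propagation in quadrature for independent sums
(half-widths add in root-sum-of-squares), and Monte Carlo sampling from
distributions fitted to each reported interval.  Asymmetric intervals are
represented as two-piece (split) normals hinged at the reported mean, with
each half-width mapped to a one-sided sigma via the normal 97.5% quantile
(half-width / 1.96).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Family",
    "UncertainQuantity",
    "fit_from_ci",
    "combine_quadrature",
    "combine_monte_carlo",
]

_Z95 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)


class Family(str, Enum):
    normal = "normal"
    two_piece_normal = "two_piece_normal"
    lognormal = "lognormal"
    uniform = "uniform"
    point = "point"


@dataclass(frozen=True)
class UncertainQuantity:
    """A mean with 95% bounds and the distribution family fitted to them."""

    mean: float
    low: float
    high: float
    family: Family = Family.normal

    def __post_init__(self) -> None:
        if not (self.low <= self.mean <= self.high):
            raise ValueError(
                f"interval ordering violated: {self.low} <= {self.mean} <= {self.high}"
            )
        if self.family is Family.lognormal and not self.low > 0:
            raise ValueError("lognormal requires strictly positive lower bound")

    @property
    def sigma_low(self) -> float:
        return (self.mean - self.low) / _Z95

    @property
    def sigma_high(self) -> float:
        return (self.high - self.mean) / _Z95


def fit_from_ci(mean: float, low: float, high: float) -> UncertainQuantity:
    """Choose a family for a reported 95% interval.

    Symmetric intervals map to a normal (sigma = width / 3.92), degenerate
    intervals to a point mass, and asymmetric intervals to a two-piece
    normal with separate one-sided sigmas.
    """
    if not (low <= mean <= high):
        raise ValueError(f"interval ordering violated: {low} <= {mean} <= {high}")
    lo_hw = mean - low
    hi_hw = high - mean
    width = high - low
    if width == 0.0:
        return UncertainQuantity(mean, low, high, Family.point)
    if math.isclose(lo_hw, hi_hw, rel_tol=1e-9, abs_tol=1e-12 * max(1.0, abs(mean))):
        return UncertainQuantity(mean, low, high, Family.normal)
    return UncertainQuantity(mean, low, high, Family.two_piece_normal)


def combine_quadrature(quantities: Sequence[UncertainQuantity]) -> UncertainQuantity:
    """Combine independent quantities: means add; each side's half-widths
    add in quadrature (root sum of squares)."""
    if len(quantities) == 0:
        raise ValueError("cannot combine an empty collection of quantities")
    mean = sum(q.mean for q in quantities)
    lo_hw = math.sqrt(sum((q.mean - q.low) ** 2 for q in quantities))
    hi_hw = math.sqrt(sum((q.high - q.mean) ** 2 for q in quantities))
    return fit_from_ci(mean, mean - lo_hw, mean + hi_hw)


def _draw(
    q: UncertainQuantity, n: int, rng: np.random.Generator
) -> np.ndarray:
    if q.family is Family.point:
        return np.full(n, q.mean)
    if q.family is Family.normal:
        sigma = (q.high - q.low) / (2.0 * _Z95)
        return rng.normal(q.mean, sigma, n)
    if q.family is Family.two_piece_normal:
        s1, s2 = q.sigma_low, q.sigma_high
        w = s1 / (s1 + s2) if (s1 + s2) > 0 else 0.5
        below = rng.random(n) < w
        mags = np.abs(rng.standard_normal(n))
        return np.where(below, q.mean - s1 * mags, q.mean + s2 * mags)
    if q.family is Family.lognormal:
        # median at the reported mean; log-sigma from the upper bound
        s = math.log(q.high / q.mean) / _Z95 if q.high > q.mean else 0.0
        return q.mean * np.exp(rng.normal(0.0, s, n))
    if q.family is Family.uniform:
        return rng.uniform(q.low, q.high, n)
    raise ValueError(f"cannot sample family {q.family!r}")


def combine_monte_carlo(
    quantities: Sequence[UncertainQuantity],
    n_draws: int = 100_000,
    seed: int | None = 0,
    nonnegative: bool = True,
) -> UncertainQuantity:
    """Combine independent quantities by sampling.

    Each quantity is drawn from its fitted family, draws are summed, and
    the empirical mean and 2.5/97.5 percentiles are reported.  With
    ``nonnegative`` (the default), draws for quantities whose reported
    interval is entirely nonnegative are truncated at 0 — mitigation
    potentials cannot go negative.  Deterministic for a given seed.
    """
    if len(quantities) == 0:
        raise ValueError("cannot combine an empty collection of quantities")
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for stable percentiles")
    rng = np.random.default_rng(seed)
    total = np.zeros(n_draws)
    for q in quantities:
        draws = _draw(q, n_draws, rng)
        if nonnegative and q.low >= 0.0:
            np.clip(draws, 0.0, None, out=draws)
        total += draws
    mean = float(total.mean())
    lo, hi = np.percentile(total, [2.5, 97.5])
    lo = min(float(lo), mean)
    hi = max(float(hi), mean)
    return fit_from_ci(mean, lo, hi)
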