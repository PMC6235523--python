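"""Marginal abatement cost (MAC) structure for the portfolio.

Each pathway carries cumulative-mitigation tranches at carbon-price
ceilings (USD per Mg CO2e); merging them across pathways yields a portfolio
step function: cumulative mitigation available at or below each price.
The reported granularity is three price points (USD 10, 50, 100), so each
pathway's curve is a 3-step function; finer tranche sets merge the same
way.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import PathwayParams

__all__ = ["MACCurve", "build_mac", "mitigation_at_price", "fraction_of_maximum"]


@dataclass(frozen=True)
class MACCurve:
    """Portfolio price -> cumulative mitigation step function.

    ``points`` are (price ceiling USD/Mg CO2e, cumulative Tg CO2e yr-1),
    strictly increasing in price and nondecreasing in quantity.
    ``maximum`` is the unconstrained portfolio total the curve saturates
    toward.
    """

    points: tuple[tuple[float, float], ...]
    maximum: float = math.inf

    def __post_init__(self) -> None:
        prev_p, prev_q = -math.inf, -math.inf
        for price, cum in self.points:
            if price <= prev_p:
                raise ValueError("MAC prices must be strictly increasing")
            if cum < prev_q - 1e-9:
                raise ValueError("MAC cumulative quantities must be nondecreasing")
            prev_p, prev_q = price, cum
        if self.points and self.points[-1][1] > self.maximum + 1e-9:
            raise ValueError(
                f"cumulative mitigation {self.points[-1][1]} exceeds portfolio "
                f"maximum {self.maximum}"
            )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=["price_usd", "cumulative_tg"])
        if math.isfinite(self.maximum):
            df["fraction_of_maximum"] = df["cumulative_tg"] / self.maximum
        return df


def build_mac(pathways: Sequence[PathwayParams]) -> MACCurve:
    """Merge per-pathway cost tranches into the portfolio MAC curve.

    The merged curve is evaluated at the union of all price ceilings; the
    cumulative quantity at price P is the sum over pathways of each
    pathway's tranche value at its largest ceiling <= P.  Tranche validity
    (quantity within the pathway maximum) is enforced by
    :class:`~ncskit.core.PathwayParams`; an inconsistent ad hoc tranche
    raises here, naming the pathway.
    """
    prices = sorted({price for p in pathways for price, _ in p.cost_tranches})
    points = []
    for price in prices:
        cum = 0.0
        for p in pathways:
            v = _tranche_at(p, price)
            if v > p.mitigation_mean + 1e-9:
                raise ValueError(
                    f"pathway {p.id!r}: tranche quantity {v} exceeds its "
                    f"maximum {p.mitigation_mean}"
                )
            cum += v
        points.append((price, cum))
    maximum = sum(p.mitigation_mean for p in pathways)
    return MACCurve(tuple(points), maximum=maximum)


def _tranche_at(p: PathwayParams, price: float) -> float:
    best = 0.0
    for ceiling, cum in p.cost_tranches:
        if ceiling <= price:
            best = cum
    return best


def mitigation_at_price(curve: MACCurve, price: float) -> float:
    """Cumulative mitigation (Tg CO2e yr-1) available at or below ``price``.

    Step-function evaluation: the quantity at the largest curve price
    <= ``price``; 0 below the first step.
    """
    if price < 0:
        raise ValueError("price must be >= 0")
    prices = [p for p, _ in curve.points]
    i = bisect.bisect_right(prices, price)
    if i == 0:
        return 0.0
    return curve.points[i - 1][1]


def fraction_of_maximum(curve: MACCurve, price: float) -> float:
    """Share of the unconstrained portfolio maximum realizable at ``price``."""
    if not math.isfinite(curve.maximum) or curve.maximum <= 0:
        raise ValueError("curve has no finite positive maximum")
    return mitigation_at_price(curve, price) / curve.maximum
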