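"""Portfolio assembly, headline summaries, and tabular reporting.

The report mirrors the standard presentation of an NCS assessment: one row
per pathway with its maximum mitigation, 95% CI, the mitigation available
below the USD 10/50/100 price ceilings, co-benefit flags, and the years to
saturation; plus a headline block (portfolio total with CI, share of
national net emissions, price-point fractions, and the carbon-pool
decomposition).

Rounding conventions: totals are carried unrounded; formatted output
prints Tg and percentages at the nearest integer and Pg at 2 significant
figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .abatement import build_mac, mitigation_at_price
from .core import (
    COBENEFITS,
    POOLS,
    MitigationEstimate,
    PathwayParams,
    Portfolio,
    estimate_from_params,
    percent_of_reference,
)
from .uncertainty import (
    UncertainQuantity,
    combine_monte_carlo,
    combine_quadrature,
    fit_from_ci,
)

__all__ = [
    "aggregate_portfolio",
    "portfolio_from_params",
    "top_k_share",
    "pool_decomposition",
    "results_table",
    "write_results",
    "read_results",
    "format_pg",
    "summary_text",
]

#: National net GHG emissions in the 2016 reference year, Tg CO2e yr-1.
REFERENCE_NET_EMISSIONS_TG = 5794.5


def aggregate_portfolio(
    estimates: Sequence[MitigationEstimate],
    method: str = "quadrature",
    n_draws: int = 100_000,
    seed: int | None = 0,
    reference_net_emissions: float = REFERENCE_NET_EMISSIONS_TG,
) -> Portfolio:
    """Sum pathway estimates into a portfolio with a propagated 95% CI.

    ``method`` selects the CI combiner: ``"quadrature"`` (default;
    deterministic root-sum-of-squares of half-widths) or ``"mc"``
    (Monte Carlo over the fitted interval families).  The portfolio mean is
    always the exact sum of pathway means; the combiner supplies only the
    interval.  Duplicate pathway ids are rejected — each intervention may
    be counted once.
    """
    if len(estimates) == 0:
        raise ValueError("cannot aggregate an empty portfolio")
    quantities = [fit_from_ci(e.mean, e.ci[0], e.ci[1]) for e in estimates]
    if method == "quadrature":
        combined = combine_quadrature(quantities)
    elif method == "mc":
        combined = combine_monte_carlo(quantities, n_draws=n_draws, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}; use 'quadrature' or 'mc'")
    total_mean = sum(e.mean for e in estimates)
    # anchor the interval to the exact sum of means
    ci = (
        min(combined.low, total_mean),
        max(combined.high, total_mean),
    )
    return Portfolio(
        estimates=tuple(estimates),
        total_mean=total_mean,
        total_ci=ci,
        reference_net_emissions=reference_net_emissions,
    )


def portfolio_from_params(
    pathways: Sequence[PathwayParams], **kwargs
) -> Portfolio:
    """Aggregate a portfolio directly from a pathway parameter table."""
    return aggregate_portfolio([estimate_from_params(p) for p in pathways], **kwargs)


def top_k_share(portfolio: Portfolio, k: int) -> float:
    """Percent of the portfolio total held by the k largest pathways."""
    n = len(portfolio.estimates)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    means = sorted((e.mean for e in portfolio.estimates), reverse=True)
    return percent_of_reference(sum(means[:k]), portfolio.total_mean)


def pool_decomposition(portfolio: Portfolio) -> dict[str, float]:
    """Mitigation-weighted carbon-pool fractions over
    {biomass, soil, avoided_ch4_n2o}; sums to 1 up to rounding."""
    totals = dict.fromkeys(POOLS, 0.0)
    for e in portfolio.estimates:
        if not e.by_pool:
            raise ValueError(f"pathway {e.pathway_id!r} has no pool decomposition")
        for pool, v in e.by_pool.items():
            totals[pool] += v
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("portfolio has zero total mitigation")
    return {pool: v / grand for pool, v in totals.items()}


def format_pg(total_tg: float, sig_figs: int = 2) -> str:
    """Format a Tg total in Pg at 2 significant figures (e.g. '1.2')."""
    pg = total_tg / 1000.0
    if pg == 0:
        return "0.0"
    digits = sig_figs - 1 - int(math.floor(math.log10(abs(pg))))
    text = f"{round(pg, digits):.{max(digits, 0)}f}"
    # 2 s.f. of 0.90 prints as the conventional "0.9"
    if "." in text:
        text = text.rstrip("0").rstrip(".")
        if "." not in text:
            text += ".0"
    return text


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = [
    "pathway",
    "maximum_tg",
    "ci_low_tg",
    "ci_high_tg",
    "cost10_tg",
    "cost50_tg",
    "cost100_tg",
    "saturation_yr",
] + [f"cobenefit_{c}" for c in COBENEFITS]


def results_table(pathways: Sequence[PathwayParams]) -> pd.DataFrame:
    """One row per pathway: maximum, CI, price-constrained mitigation,
    saturation, and co-benefit flags (0/1 metadata passthrough)."""
    rows = []
    for p in sorted(pathways, key=lambda q: -q.mitigation_mean):
        tranche = dict(p.cost_tranches)
        row = {
            "pathway": p.id,
            "maximum_tg": p.mitigation_mean,
            "ci_low_tg": p.ci_low,
            "ci_high_tg": p.ci_high,
            "cost10_tg": tranche.get(10.0, 0.0),
            "cost50_tg": tranche.get(50.0, 0.0),
            "cost100_tg": tranche.get(100.0, 0.0),
            "saturation_yr": p.saturation_years,
        }
        for c in COBENEFITS:
            row[f"cobenefit_{c}"] = int(c in p.cobenefits)
        if not (
            p.mitigation_mean + 1e-9
            >= row["cost100_tg"]
            >= row["cost50_tg"]
            >= row["cost10_tg"]
            >= 0.0
        ):
            raise ValueError(f"pathway {p.id!r}: cost columns must be nested")
        rows.append(row)
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def write_results(pathways: Sequence[PathwayParams], path: str | Path) -> None:
    # repr-precision floats so totals survive the round trip bit-identically
    results_table(pathways).to_csv(path, index=False, float_format=None)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    return df


def summary_text(
    pathways: Sequence[PathwayParams],
    method: str = "quadrature",
    seed: int | None = 0,
    gwp_note: str = "AR5 GWP100 (CH4 28, N2O 265); tidal wetlands on SGWP (CH4 45)",
) -> str:
    """Plain-text headline block for a pathway parameter table."""
    portfolio = portfolio_from_params(pathways, method=method, seed=seed)
    curve = build_mac(pathways)
    total = portfolio.total_mean
    lo, hi = portfolio.total_ci
    pct_ref = percent_of_reference(total, portfolio.reference_net_emissions)
    pools = pool_decomposition(portfolio)
    lines = [
        "NCS portfolio summary",
        "=====================",
        f"pathways:               {len(pathways)}",
        f"maximum mitigation:     {format_pg(total)} Pg CO2e/yr "
        f"({total:.1f} Tg; 95% CI {format_pg(lo)} to {format_pg(hi)} Pg)",
        f"share of net emissions: {pct_ref:.1f}% of "
        f"{portfolio.reference_net_emissions:.1f} Tg CO2e/yr "
        f"(~{round(pct_ref)}%)",
        "pool decomposition:     "
        + ", ".join(f"{k} {100 * v:.1f}%" for k, v in pools.items()),
    ]
    for price in (10.0, 50.0, 100.0):
        tg = mitigation_at_price(curve, price)
        lines.append(
            f"available at USD {price:>5.0f}: {tg:.1f} Tg CO2e/yr "
            f"({100 * tg / total:.1f}% of maximum)"
        )
    lines.append(f"CI method:              {method} (seed={seed})")
    lines.append(f"CO2e basis:             {gwp_note}")
    return "\n".join(lines) + "\n"
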