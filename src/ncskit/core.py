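"""Shared domain types and the generic accounting arithmetic.

Every pathway estimate in the package ultimately reduces to an
``extent x rate`` product expressed in Tg CO2e yr-1, plus a conversion of
CH4 and N2O mass fluxes onto the CO2-equivalent scale under a chosen
warming-potential metric.  Unit canon throughout the package:

* extents in Mha
* per-area fluxes in Mg CO2e ha-1 yr-1
* totals in Tg CO2e yr-1  (1 Mha x 1 Mg ha-1 = 1 Tg)
* Pg appears only in formatted reports, at 2 significant figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "C_TO_CO2",
    "PATHWAY_IDS",
    "Category",
    "GWPSet",
    "GWP_AR5_100",
    "SGWP_TIDAL",
    "GasAmount",
    "PathwayParams",
    "MitigationEstimate",
    "Portfolio",
    "to_co2e",
    "area_times_rate",
    "percent_of_reference",
    "read_parameter_table",
    "write_parameter_table",
]

#: Mass ratio converting Mg C to Mg CO2.
C_TO_CO2 = 44.0 / 12.0

#: The 21 intervention pathways, in conventional reporting order.
PATHWAY_IDS = (
    "reforestation",
    "natural_forest_management",
    "avoided_grassland_conversion",
    "cover_crops",
    "biochar",
    "alley_cropping",
    "cropland_nutrient_management",
    "avoided_forest_conversion",
    "fire_management",
    "tidal_wetland_restoration",
    "urban_reforestation",
    "improved_plantations",
    "grazing_optimization",
    "improved_manure_management",
    "improved_rice_management",
    "peatland_restoration",
    "grassland_restoration",
    "windbreaks",
    "legumes_in_pastures",
    "avoided_seagrass_loss",
    "seagrass_restoration",
)

POOLS = ("biomass", "soil", "avoided_ch4_n2o")

COBENEFITS = ("air", "biodiversity", "soil", "water")


class Category(str, Enum):
    forest = "forest"
    agriculture_grassland = "agriculture_grassland"
    wetland = "wetland"


class GWPScheme(str, Enum):
    GWP = "GWP"
    SGWP = "SGWP"


@dataclass(frozen=True)
class GWPSet:
    """CO2-equivalence factors for CH4 and N2O.

    ``scheme`` distinguishes the conventional pulse-emission global warming
    potential (GWP) from the sustained-flux GWP (SGWP) appropriate for a
    persistent change in wetland CH4 flux.
    """

    ch4_factor: float
    n2o_factor: float
    horizon_years: int = 100
    scheme: GWPScheme = GWPScheme.GWP

    def __post_init__(self) -> None:
        if not (self.ch4_factor > 0 and self.n2o_factor > 0):
            raise ValueError("GWP factors must be positive")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")


#: AR5 100-year GWP (CH4 28, N2O 265) — the package default.
GWP_AR5_100 = GWPSet(ch4_factor=28.0, n2o_factor=265.0, horizon_years=100)

#: Sustained-flux GWP used for tidal-wetland CH4 accounting (CH4 45).
SGWP_TIDAL = GWPSet(
    ch4_factor=45.0, n2o_factor=270.0, horizon_years=100, scheme=GWPScheme.SGWP
)


@dataclass(frozen=True)
class GasAmount:
    """Annual gas fluxes by species, in native mass units (Tg of gas yr-1).

    Negative components are permitted: they represent net uptake.
    """

    co2: float = 0.0
    ch4: float = 0.0
    n2o: float = 0.0

    def __post_init__(self) -> None:
        for name in ("co2", "ch4", "n2o"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite {name} flux: {v!r}")

    def __add__(self, other: "GasAmount") -> "GasAmount":
        return GasAmount(
            self.co2 + other.co2, self.ch4 + other.ch4, self.n2o + other.n2o
        )


def to_co2e(gas: GasAmount, gwp: GWPSet) -> float:
    """Convert a :class:`GasAmount` to Tg CO2e yr-1 under ``gwp``.

    Linear in every component: CO2 passes through at factor 1.
    """
    return gas.co2 + gas.ch4 * gwp.ch4_factor + gas.n2o * gwp.n2o_factor


def area_times_rate(extent_mha: float, rate_mg_per_ha: float) -> float:
    """``extent (Mha) x rate (Mg CO2e ha-1 yr-1) -> Tg CO2e yr-1``.

    The Mha x Mg/ha product lands on Tg with no numeric factor
    (1e6 ha x Mg/ha = 1e6 Mg = 1 Tg).  Rates may be negative (penalty
    terms); extents may not.
    """
    if not math.isfinite(extent_mha) or extent_mha < 0:
        raise ValueError(f"extent must be finite and >= 0, got {extent_mha!r}")
    return extent_mha * rate_mg_per_ha


def percent_of_reference(total: float, reference: float) -> float:
    """Express ``total`` as an (unrounded) percentage of ``reference``."""
    if not reference > 0:
        raise ValueError(f"reference must be positive, got {reference!r}")
    return 100.0 * total / reference


@dataclass(frozen=True)
class PathwayParams:
    """One intervention's extent, flux, CI, cost structure, and metadata.

    ``flux_per_area`` is None for pathways whose mitigation is estimated as
    a total rather than an area x rate product.  ``cost_tranches`` is the
    cumulative mitigation available at or below each carbon-price ceiling
    (USD per Mg CO2e); ``math.inf`` denotes the unconstrained maximum.
    """

    id: str
    category: Category
    extent: float | None  # Mha
    flux_per_area: float | None  # Mg CO2e ha-1 yr-1
    mitigation_mean: float  # Tg CO2e yr-1
    ci_low: float
    ci_high: float
    pool_split: Mapping[str, float]  # fractions over POOLS
    saturation_years: float
    cost_tranches: tuple[tuple[float, float], ...]  # (price ceiling, cumulative Tg)
    cobenefits: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.id not in PATHWAY_IDS:
            raise ValueError(
                f"unknown pathway id {self.id!r}; valid ids: {', '.join(PATHWAY_IDS)}"
            )
        if not (self.ci_low <= self.mitigation_mean <= self.ci_high):
            raise ValueError(
                f"{self.id}: CI ordering violated "
                f"({self.ci_low} <= {self.mitigation_mean} <= {self.ci_high})"
            )
        if self.extent is not None and self.extent < 0:
            raise ValueError(f"{self.id}: extent must be >= 0")
        if set(self.pool_split) - set(POOLS):
            raise ValueError(f"{self.id}: unknown pools in pool_split")
        if abs(sum(self.pool_split.values()) - 1.0) > 1e-9:
            raise ValueError(f"{self.id}: pool_split must sum to 1")
        if self.cobenefits - set(COBENEFITS):
            raise ValueError(f"{self.id}: unknown co-benefit tags")
        prev_p, prev_q = -math.inf, -math.inf
        for price, cum in self.cost_tranches:
            if price <= prev_p:
                raise ValueError(f"{self.id}: tranche prices must increase")
            if cum < prev_q - 1e-9:
                raise ValueError(f"{self.id}: tranche quantities must be nondecreasing")
            prev_p, prev_q = price, cum
        if self.cost_tranches:
            last = self.cost_tranches[-1][1]
            if last > self.mitigation_mean + 1e-9:
                raise ValueError(
                    f"{self.id}: tranche quantity {last} exceeds pathway maximum "
                    f"{self.mitigation_mean}"
                )


@dataclass(frozen=True)
class MitigationEstimate:
    """A pathway's mitigation: mean, 95% CI, and gas/pool decomposition."""

    pathway_id: str
    mean: float  # Tg CO2e yr-1
    ci: tuple[float, float]
    by_gas: GasAmount = field(default_factory=GasAmount)  # already in CO2e
    by_pool: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo <= self.mean + 1e-9 and self.mean <= hi + 1e-9):
            raise ValueError(
                f"{self.pathway_id}: CI ({lo}, {hi}) does not bracket mean {self.mean}"
            )
        if self.by_pool:
            s = sum(self.by_pool.values())
            if abs(s - self.mean) > 1e-6 * max(1.0, abs(self.mean)):
                raise ValueError(
                    f"{self.pathway_id}: by_pool sums to {s}, mean is {self.mean}"
                )


@dataclass(frozen=True)
class Portfolio:
    """The pathway estimates plus combined totals and CI.

    ``reference_net_emissions`` is the national net-emission figure the
    portfolio is expressed against (Tg CO2e yr-1).
    """

    estimates: tuple[MitigationEstimate, ...]
    total_mean: float
    total_ci: tuple[float, float]
    reference_net_emissions: float = 5794.5

    def __post_init__(self) -> None:
        ids = [e.pathway_id for e in self.estimates]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway ids (double counting): {dupes}")
        if len(ids) > len(PATHWAY_IDS):
            raise ValueError("more estimates than defined pathways")
        s = sum(e.mean for e in self.estimates)
        if abs(s - self.total_mean) > 1e-6 * max(1.0, abs(s)):
            raise ValueError(f"total_mean {self.total_mean} != sum of means {s}")


# ---------------------------------------------------------------------------
# Parameter-table I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "id",
    "category",
    "extent_mha",
    "flux_mgco2e_ha_yr",
    "mitigation_tg",
    "ci_low_tg",
    "ci_high_tg",
    "frac_biomass",
    "frac_soil",
    "frac_avoided",
    "saturation_yr",
    "cost10_tg",
    "cost50_tg",
    "cost100_tg",
    "cobenefits",
]

_PRICE_POINTS = (10.0, 50.0, 100.0)


def params_to_frame(pathways: Sequence[PathwayParams]) -> pd.DataFrame:
    """Render pathway parameters as the canonical one-row-per-pathway table."""
    rows = []
    for p in pathways:
        tranche = dict(p.cost_tranches)
        rows.append(
            {
                "id": p.id,
                "category": p.category.value,
                "extent_mha": p.extent,
                "flux_mgco2e_ha_yr": p.flux_per_area,
                "mitigation_tg": p.mitigation_mean,
                "ci_low_tg": p.ci_low,
                "ci_high_tg": p.ci_high,
                "frac_biomass": p.pool_split.get("biomass", 0.0),
                "frac_soil": p.pool_split.get("soil", 0.0),
                "frac_avoided": p.pool_split.get("avoided_ch4_n2o", 0.0),
                "saturation_yr": p.saturation_years,
                "cost10_tg": tranche.get(10.0, 0.0),
                "cost50_tg": tranche.get(50.0, 0.0),
                "cost100_tg": tranche.get(100.0, 0.0),
                "cobenefits": ";".join(c for c in COBENEFITS if c in p.cobenefits),
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def frame_to_params(df: pd.DataFrame) -> list[PathwayParams]:
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        tranches = tuple(
            (price, float(r[col]))
            for price, col in zip(_PRICE_POINTS, ("cost10_tg", "cost50_tg", "cost100_tg"))
        )
        cob = r["cobenefits"]
        cob = frozenset(cob.split(";")) if isinstance(cob, str) and cob else frozenset()
        out.append(
            PathwayParams(
                id=r["id"],
                category=Category(r["category"]),
                extent=None if pd.isna(r["extent_mha"]) else float(r["extent_mha"]),
                flux_per_area=(
                    None if pd.isna(r["flux_mgco2e_ha_yr"]) else float(r["flux_mgco2e_ha_yr"])
                ),
                mitigation_mean=float(r["mitigation_tg"]),
                ci_low=float(r["ci_low_tg"]),
                ci_high=float(r["ci_high_tg"]),
                pool_split={
                    "biomass": float(r["frac_biomass"]),
                    "soil": float(r["frac_soil"]),
                    "avoided_ch4_n2o": float(r["frac_avoided"]),
                },
                saturation_years=float(r["saturation_yr"]),
                cost_tranches=tranches,
                cobenefits=cob,
            )
        )
    return out


def write_parameter_table(pathways: Sequence[PathwayParams], path: str | Path) -> None:
    params_to_frame(pathways).to_csv(path, index=False)


def read_parameter_table(path: str | Path) -> list[PathwayParams]:
    # round_trip parsing so serialized tables reproduce totals bit-identically
    return frame_to_params(pd.read_csv(path, float_precision="round_trip"))


def estimate_from_params(p: PathwayParams, gwp: GWPSet = GWP_AR5_100) -> MitigationEstimate:
    """Build a :class:`MitigationEstimate` directly from tabulated parameters.

    The avoided-CH4/N2O pool share is expressed in the gas decomposition as
    CO2e (no back-conversion to native gas mass is attempted at table level).
    """
    by_pool = {pool: p.pool_split.get(pool, 0.0) * p.mitigation_mean for pool in POOLS}
    by_gas = GasAmount(co2=by_pool["biomass"] + by_pool["soil"] + by_pool["avoided_ch4_n2o"])
    return MitigationEstimate(
        pathway_id=p.id,
        mean=p.mitigation_mean,
        ci=(p.ci_low, p.ci_high),
        by_gas=by_gas,
        by_pool=by_pool,
    )
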