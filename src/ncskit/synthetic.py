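"""Synthetic inputs: toy landscapes and the pathway parameter fixture.

The pipeline's national-scale inputs (land-cover, tree-cover, soil-carbon
and climate rasters; the per-pathway parameter table) cannot travel with
the package, so this module generates stand-ins with the statistical
structure the analysis assumes.

Two parameter-table modes exist.  *Fixture* mode emits the headline
pathway values as published — the ten largest maxima (307, 267, 107, 103,
95, 82, 52, 38, 18, 12 Tg CO2e yr-1) plus eleven smaller pathways summing
to 122 Tg — with price tranches and carbon-pool splits constrained to
every published aggregate (299/914/1095 Tg below USD 10/50/100; 63/29/7%
biomass/soil/avoided pools).  The eleven small maxima, the non-headline
tranche entries, and all per-pathway CIs are synthetic: they are not
published individually at this granularity, so they are back-solved
against the aggregates (CIs are proportional to each mean, scaled so the
portfolio quadrature interval is 900-1600 Tg).  *Random* mode perturbs the
fixture for property tests.

Landscape generation is fully deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

import numpy as np

from .core import Category, PathwayParams
from .grids import LAND_COVER_CODES, LandscapeGrid

__all__ = [
    "SyntheticConfig",
    "generate_landscape",
    "generate_parameter_table",
    "generate_conversion_events",
    "FIXTURE_ROWS",
]

# id, category, max Tg, cost10, cost50, cost100, frac_biomass, frac_soil,
# extent Mha (None if not area-based), flux Mg CO2e/ha/yr, saturation yr,
# co-benefit tags.  frac_avoided = 1 - biomass - soil.
FIXTURE_ROWS: tuple[tuple, ...] = (
    ("reforestation", "forest", 307.0, 0.0, 255.0, 295.0, 0.975, 0.025,
     51.6, 307.0 / 51.6, 90, "air;biodiversity;soil;water"),
    ("natural_forest_management", "forest", 267.0, 64.0, 215.0, 245.0, 1.0, 0.0,
     120.0, 267.0 / 120.0, 30, "biodiversity;water"),
    ("avoided_grassland_conversion", "agriculture_grassland", 107.0, 24.0, 85.0,
     100.0, 0.19, 0.81, 107.0 / (125.0 / 0.81), 125.0 / 0.81, 67,
     "biodiversity;soil;water"),
    ("cover_crops", "agriculture_grassland", 103.0, 100.0, 101.0, 102.0, 0.0, 1.0,
     88.0, 0.32 * 44.0 / 12.0, 27, "soil;water"),
    ("biochar", "agriculture_grassland", 95.0, 0.0, 40.0, 75.0, 0.0, 1.0,
     None, None, 100, "soil"),
    ("alley_cropping", "agriculture_grassland", 82.0, 0.0, 43.0, 70.0, 1.0, 0.0,
     15.4, 82.0 / 15.4, 45, "biodiversity;soil;water"),
    ("cropland_nutrient_management", "agriculture_grassland", 52.0, 28.0, 44.0,
     48.0, 0.0, 0.0, None, None, math.inf, "air;soil;water"),
    ("avoided_forest_conversion", "forest", 38.0, 37.0, 37.0, 38.0, 1.0, 0.0,
     None, None, 67, "air;biodiversity;soil;water"),
    ("fire_management", "forest", 18.0, 0.0, 10.0, 16.0, 1.0, 0.0,
     20.0, 18.0 / 20.0, 20, "air;biodiversity;water"),
    ("tidal_wetland_restoration", "wetland", 12.0, 0.0, 6.0, 10.0, 0.0, 0.0,
     1.7 * 0.27, 12.0 / (1.7 * 0.27), math.inf, "biodiversity;water"),
    # --- the eleven smaller pathways (synthetic maxima summing to 122;
    # each <= 12 so the ten headline pathways are the ten largest) ---
    ("urban_reforestation", "forest", 12.0, 0.0, 5.0, 9.0, 1.0, 0.0,
     1.2, 10.0, 90, "air;water"),
    ("improved_plantations", "forest", 12.0, 5.0, 10.0, 12.0, 1.0, 0.0,
     None, None, 30, "biodiversity;water"),
    ("grazing_optimization", "agriculture_grassland", 12.0, 6.0, 10.0, 12.0,
     0.0, 1.0, 160.0, 12.0 / 160.0, 30, "biodiversity;soil"),
    ("improved_manure_management", "agriculture_grassland", 12.0, 12.0, 12.0,
     12.0, 0.0, 0.0, None, None, math.inf, "air;water"),
    ("improved_rice_management", "agriculture_grassland", 12.0, 8.0, 10.0,
     12.0, 0.0, 0.0, 1.2, 10.0, math.inf, "air;water"),
    ("peatland_restoration", "wetland", 12.0, 4.0, 9.0, 11.0, 0.3, 0.7,
     12.0 / 8.2, 8.2, 100, "biodiversity;soil;water"),
    ("grassland_restoration", "agriculture_grassland", 12.0, 3.0, 5.0, 7.0,
     0.3, 0.7, 2.1, 12.0 / 2.1, 27, "biodiversity;soil;water"),
    ("windbreaks", "agriculture_grassland", 5.0, 5.0, 5.0, 5.0, 0.8, 0.2,
     0.88, 5.0 / 0.88, 45, "air;soil"),
    ("legumes_in_pastures", "agriculture_grassland", 12.0, 3.0, 4.0, 7.0,
     0.0, 1.0, 10.0, 1.2, 27, "soil"),
    ("avoided_seagrass_loss", "wetland", 12.0, 0.0, 5.0, 6.0, 0.15, 0.85,
     1.0, 12.0, 67, "biodiversity;water"),
    ("seagrass_restoration", "wetland", 9.0, 0.0, 3.0, 3.0, 0.0, 1.0,
     1.35, 9.0 / 1.35, 100, "biodiversity;water"),
)

# Portfolio 95% CI half-widths (Tg) the fixture CIs are scaled to.
_PORTFOLIO_LO_HW = 303.0  # 1203 - 900
_PORTFOLIO_HI_HW = 397.0  # 1600 - 1203


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the toy landscape and parameter-table generators.

    The default domain is a 100 x 100 grid of 100-ha cells (a 1-Mha toy
    landscape).  Soil C is lognormal with mean 122 Mg C ha-1 (the stock at
    which a 28% loss emits ~125 Mg CO2e ha-1) and CV 0.3; climate fields
    are smooth north-south (temperature) and west-east (precipitation)
    gradients plus noise; masks are drawn with class-conditional
    probabilities.  ``ci_rel_noise`` controls random-mode perturbation of
    the parameter table.
    """

    seed: int = 0
    shape: tuple[int, int] = (100, 100)
    cell_area: float = 100.0  # ha
    class_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "forest": 0.30,
            "grassland": 0.20,
            "shrubland": 0.10,
            "cropland": 0.20,
            "pasture": 0.08,
            "urban": 0.05,
            "water": 0.02,
            "wetland": 0.05,
        }
    )
    soil_c_mean: float = 122.0  # Mg C ha-1
    soil_c_cv: float = 0.3
    mat_range: tuple[float, float] = (5.0, 20.0)  # degC, north -> south
    map_range: tuple[float, float] = (300.0, 1400.0)  # mm, west -> east
    conifer_beta: tuple[float, float] = (2.0, 2.0)
    mask_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "impervious": {"urban": 0.8, "default": 0.02},
            "major_road": {"default": 0.03},
            "histosol": {"wetland": 0.5, "forest": 0.05, "default": 0.02},
            "protected": {"default": 0.10},
        }
    )
    conversion_rates: Mapping[str, float] = field(
        default_factory=lambda: {"grassland": 0.006, "shrubland": 0.003, "forest": 0.001}
    )
    ci_rel_noise: float = 0.0  # random-mode perturbation scale

    def __post_init__(self) -> None:
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities sum to {total}, expected 1")
        unknown = set(self.class_probs) - set(LAND_COVER_CODES)
        if unknown:
            raise ValueError(f"unknown land-cover classes: {sorted(unknown)}")
        if self.soil_c_mean <= 0 or self.soil_c_cv < 0:
            raise ValueError("soil C distribution parameters out of range")
        for cls, rate in self.conversion_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"conversion rate for {cls!r} outside [0, 1]")


def generate_landscape(cfg: SyntheticConfig | None = None) -> LandscapeGrid:
    """Sample a toy landscape; bit-reproducible for a fixed seed."""
    if cfg is None:
        cfg = SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    nrows, ncols = cfg.shape
    classes = list(cfg.class_probs)
    probs = np.array([cfg.class_probs[c] for c in classes])
    codes = np.array([LAND_COVER_CODES[c] for c in classes])
    draw = rng.choice(len(classes), size=(nrows, ncols), p=probs)
    land_cover = codes[draw]

    # tree cover: forests above the 25% threshold, everything else below
    tree_cover = rng.uniform(0.0, 24.0, size=(nrows, ncols))
    forest = land_cover == LAND_COVER_CODES["forest"]
    tree_cover[forest] = rng.uniform(40.0, 95.0, size=int(forest.sum()))
    water_urban = np.isin(
        land_cover, [LAND_COVER_CODES["water"], LAND_COVER_CODES["urban"]]
    )
    tree_cover[water_urban] *= 0.3

    sigma2 = math.log(1.0 + cfg.soil_c_cv**2)
    mu = math.log(cfg.soil_c_mean) - sigma2 / 2.0
    soil_c = rng.lognormal(mu, math.sqrt(sigma2), size=(nrows, ncols))

    row_frac = np.linspace(0.0, 1.0, nrows)[:, None] * np.ones((1, ncols))
    col_frac = np.ones((nrows, 1)) * np.linspace(0.0, 1.0, ncols)[None, :]
    mat = (
        cfg.mat_range[0]
        + (cfg.mat_range[1] - cfg.mat_range[0]) * row_frac
        + rng.normal(0.0, 0.5, size=(nrows, ncols))
    )
    map_mm = np.maximum(
        cfg.map_range[0]
        + (cfg.map_range[1] - cfg.map_range[0]) * col_frac
        + rng.normal(0.0, 40.0, size=(nrows, ncols)),
        0.0,
    )

    conifer = np.zeros((nrows, ncols))
    a, b = cfg.conifer_beta
    conifer[forest] = rng.beta(a, b, size=int(forest.sum()))

    masks: dict[str, np.ndarray] = {"urban": land_cover == LAND_COVER_CODES["urban"]}
    code_to_class = {v: k for k, v in LAND_COVER_CODES.items()}
    cell_class = np.vectorize(code_to_class.get)(land_cover)
    for name, spec in cfg.mask_probs.items():
        p = np.full((nrows, ncols), spec.get("default", 0.0))
        for cls, pc in spec.items():
            if cls != "default":
                p[cell_class == cls] = pc
        masks[name] = rng.random((nrows, ncols)) < p

    return LandscapeGrid(
        cell_area=cfg.cell_area,
        land_cover=land_cover,
        tree_cover=tree_cover,
        soil_c_1m=soil_c,
        mat=mat,
        map_mm=map_mm,
        conifer_frac=conifer,
        masks=masks,
    )


def generate_parameter_table(
    cfg: SyntheticConfig | None = None, mode: str = "fixture"
) -> list[PathwayParams]:
    """Emit the 21-pathway parameter table.

    ``mode="fixture"`` returns the published-headline table described in
    the module docstring; ``mode="random"`` perturbs means, CIs, and
    tranches by ``cfg.ci_rel_noise`` (relative scale) for property tests.
    With noise 0, random mode equals the fixture.
    """
    if cfg is None:
        cfg = SyntheticConfig()
    if mode not in ("fixture", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    means = np.array([row[2] for row in FIXTURE_ROWS])
    scale = math.sqrt(float(np.sum(means**2)))
    rng = np.random.default_rng(cfg.seed)

    out = []
    for row in FIXTURE_ROWS:
        (pid, cat, mean, c10, c50, c100, fb, fs, extent, flux, sat, cob) = row
        lo_hw = _PORTFOLIO_LO_HW * mean / scale
        hi_hw = _PORTFOLIO_HI_HW * mean / scale
        if mode == "random" and cfg.ci_rel_noise > 0:
            factor = 1.0 + cfg.ci_rel_noise * rng.uniform(-0.5, 1.0)
            mean = mean * factor
            lo_hw *= 1.0 + cfg.ci_rel_noise * rng.random()
            hi_hw *= 1.0 + cfg.ci_rel_noise * rng.random()
            c10, c50, c100 = (min(c * factor, mean) for c in (c10, c50, c100))
        out.append(
            PathwayParams(
                id=pid,
                category=Category(cat),
                extent=extent,
                flux_per_area=flux,
                mitigation_mean=mean,
                ci_low=max(mean - lo_hw, 0.0),
                ci_high=mean + hi_hw,
                pool_split={
                    "biomass": fb,
                    "soil": fs,
                    "avoided_ch4_n2o": 1.0 - fb - fs,
                },
                saturation_years=sat,
                cost_tranches=((10.0, c10), (50.0, c50), (100.0, c100)),
                cobenefits=frozenset(cob.split(";")) if cob else frozenset(),
            )
        )
    return out


def generate_conversion_events(
    grid: LandscapeGrid,
    rates: Mapping[str, float],
    seed: int = 0,
) -> dict[str, float]:
    """Sample annual land-conversion events; return converted Mha per class.

    Each cell of a class converts independently with the class's annual
    rate, so the expected converted area is class area x rate.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for cls, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"conversion rate for {cls!r} outside [0, 1]")
        cells = grid.class_mask(cls)
        n = int(cells.sum())
        converted = int(rng.binomial(n, rate)) if n else 0
        out[cls] = converted * grid.cell_area / 1e6
    return out
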