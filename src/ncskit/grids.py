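"""Aligned raster layers for spatial eligibility screening.

Layers travel as ESRI ASCII grids (one ``.asc`` file per layer) bound
together by a small YAML manifest; in memory they live as numpy arrays on a
:class:`LandscapeGrid`.  The ASCII grid format is a 6-line whitespace header
(ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value) followed by rows of
numbers, top row first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "LAND_COVER_CODES",
    "LandscapeGrid",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: Integer codes for the land_cover layer.
LAND_COVER_CODES = {
    "forest": 1,
    "grassland": 2,
    "shrubland": 3,
    "cropland": 4,
    "pasture": 5,
    "urban": 6,
    "water": 7,
    "wetland": 8,
}
_CODE_TO_CLASS = {v: k for k, v in LAND_COVER_CODES.items()}

_LAYERS = ("land_cover", "tree_cover", "soil_c_1m", "mat", "map_mm", "conifer_frac")
_MASKS = ("urban", "impervious", "major_road", "histosol", "protected")


@dataclass
class LandscapeGrid:
    """Aligned per-cell layers over a rectangular landscape.

    All layers share one shape; ``cell_area`` is in hectares.  ``masks``
    are boolean exclusion/annotation layers.
    """

    cell_area: float  # ha
    land_cover: np.ndarray  # int codes, see LAND_COVER_CODES
    tree_cover: np.ndarray  # percent, 0-100
    soil_c_1m: np.ndarray  # Mg C ha-1 to 1 m depth
    mat: np.ndarray  # mean annual temperature, degC
    map_mm: np.ndarray  # mean annual precipitation, mm yr-1
    conifer_frac: np.ndarray  # fraction of tree cover that is conifer
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        shp = self.land_cover.shape
        for name in _LAYERS:
            arr = getattr(self, name)
            if arr.shape != shp:
                raise ValueError(f"layer {name!r} shape {arr.shape} != {shp}")
        for name, arr in self.masks.items():
            if arr.shape != shp:
                raise ValueError(f"mask {name!r} shape {arr.shape} != {shp}")
            if arr.dtype != bool:
                self.masks[name] = arr.astype(bool)
        bad = set(np.unique(self.land_cover)) - set(_CODE_TO_CLASS)
        if bad:
            raise ValueError(f"unknown land-cover codes: {sorted(bad)}")
        if np.any((self.tree_cover < 0) | (self.tree_cover > 100)):
            raise ValueError("tree_cover must lie in [0, 100]")
        if np.any((self.conifer_frac < 0) | (self.conifer_frac > 1)):
            raise ValueError("conifer_frac must lie in [0, 1]")
        if np.any(self.soil_c_1m < 0):
            raise ValueError("soil_c_1m must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.land_cover.shape

    def mask(self, name: str) -> np.ndarray:
        """Return the named boolean mask, or all-False if absent."""
        if name in self.masks:
            return self.masks[name]
        return np.zeros(self.shape, dtype=bool)

    def class_mask(self, *classes: str) -> np.ndarray:
        codes = [LAND_COVER_CODES[c] for c in classes]
        return np.isin(self.land_cover, codes)

    def class_area_mha(self, *classes: str) -> float:
        """Total area (Mha) of cells in the given land-cover classes."""
        return float(self.class_mask(*classes).sum()) * self.cell_area / 1e6

    # -- I/O -----------------------------------------------------------------

    def write(self, directory: str | Path, manifest_name: str = "landscape.yaml") -> Path:
        """Write one .asc per layer plus a YAML manifest; return manifest path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries: dict[str, str] = {}
        for name in _LAYERS:
            fname = f"{name}.asc"
            write_ascii_grid(directory / fname, getattr(self, name), self.cell_area)
            entries[name] = fname
        mask_entries: dict[str, str] = {}
        for name, arr in self.masks.items():
            fname = f"mask_{name}.asc"
            write_ascii_grid(directory / fname, arr.astype(np.int8), self.cell_area)
            mask_entries[name] = fname
        manifest = {
            "cell_area_ha": self.cell_area,
            "layers": entries,
            "masks": mask_entries,
        }
        mpath = directory / manifest_name
        mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))
        return mpath

    @classmethod
    def read(cls, manifest_path: str | Path) -> "LandscapeGrid":
        manifest_path = Path(manifest_path)
        manifest = yaml.safe_load(manifest_path.read_text())
        base = manifest_path.parent
        layers = {}
        for name in _LAYERS:
            try:
                fname = manifest["layers"][name]
            except KeyError:
                raise ValueError(f"manifest missing required layer {name!r}") from None
            arr, _ = read_ascii_grid(base / fname)
            layers[name] = arr
        layers["land_cover"] = layers["land_cover"].astype(np.int64)
        masks = {}
        for name, fname in manifest.get("masks", {}).items():
            arr, _ = read_ascii_grid(base / fname)
            masks[name] = arr.astype(bool)
        return cls(cell_area=float(manifest["cell_area_ha"]), masks=masks, **layers)


def write_ascii_grid(
    path: str | Path,
    data: np.ndarray,
    cellsize: float = 1.0,
    nodata: float = -9999.0,
) -> None:
    """Write a 2-D array as an ESRI ASCII grid."""
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError("ASCII grids are 2-D")
    nrows, ncols = data.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner 0.0\n"
        f"yllcorner 0.0\n"
        f"cellsize {cellsize}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in data:
            fh.write(" ".join(format(v, "g") for v in row))
            fh.write("\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict[str, float]]:
    """Read an ESRI ASCII grid; return (array, header dict)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0][0].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    data = np.array(rows, dtype=float)
    ncols = int(header.get("ncols", data.shape[1]))
    nrows = int(header.get("nrows", data.shape[0]))
    if data.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: grid body {data.shape} does not match header ({nrows}, {ncols})"
        )
    return data, header
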