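"""Gridded layers and zone maps.

Rasters are plain 2-D arrays on a single shared grid: an elevation surface
(metres), a population surface (persons per cell) and an integer zone map
assigning each cell to a region. No CRS handling or resampling is done —
layers must be pre-aligned. On disk the format is the ESRI ASCII grid,
which every GIS reads and which round-trips losslessly as text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_NODATA = -9999.0

#: zone label marking background (no region) cells
BACKGROUND = -1


@dataclass
class GridLayer:
    """A single-band raster: 2-D float values plus a nodata sentinel."""

    values: np.ndarray
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"grid must be 2-D, got shape {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """True where the cell holds a real value (finite and not nodata)."""
        return np.isfinite(self.values) & (self.values != self.nodata)


@dataclass
class ZoneMap:
    """Integer region labels, one per cell; ``BACKGROUND`` marks no-region cells."""

    labels: np.ndarray
    background: int = BACKGROUND

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError(f"zone map must be 2-D, got shape {self.labels.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def regions(self) -> np.ndarray:
        """Sorted region ids present in the map (background excluded)."""
        labs = np.unique(self.labels)
        return labs[labs != self.background]


def write_ascii_grid(path, layer: GridLayer, cellsize: float = 1000.0) -> None:
    """Write an ESRI ASCII grid. Values are printed with full float precision
    so a write→read round trip is bit-exact."""
    nrows, ncols = layer.shape
    vals = np.where(layer.valid_mask(), layer.values, layer.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {float(cellsize)!r}\n")
        fh.write(f"NODATA_value {float(layer.nodata)!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> GridLayer:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or any GIS)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.strip().partition(" ")
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # optional NODATA line absent
                break
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    return GridLayer(values=data, nodata=nodata)


def write_zone_map(path, zones: ZoneMap, cellsize: float = 1000.0) -> None:
    layer = GridLayer(values=zones.labels.astype(float), nodata=float(zones.background))
    write_ascii_grid(path, layer, cellsize=cellsize)


def read_zone_map(path) -> ZoneMap:
    layer = read_ascii_grid(path)
    return ZoneMap(labels=layer.values.astype(int), background=int(layer.nodata))
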