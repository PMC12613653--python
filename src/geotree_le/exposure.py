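"""Population-weighted zonal exposure.

For a region p with cells i, the population-weighted mean of a layer is

    wX_p = sum_i w_ip * X_ip,   w_ip = pop_ip / sum_i pop_ip,

so the exposure reflects where people actually live rather than raw area.
Applied to elevation this yields the population-weighted elevation used to
type regions; the same formula serves any aligned layer (NDVI, PM2.5, ...).

Cells where either the value layer or the population layer is nodata are
excluded from both the numerator and the weight sum (weights renormalise
over the valid cells). A zone with zero total valid population gets NaN and
a warning — an exposure there is undefined, never zero.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .grids import GridLayer, ZoneMap

logger = logging.getLogger(__name__)


def weighted_zonal_mean(
    layer: GridLayer, population: GridLayer, zones: ZoneMap
) -> dict[int, float]:
    """Population-weighted mean of ``layer`` per zone.

    Returns a dict region id -> weighted mean (layer units); NaN flags zones
    with no valid population.
    """
    if layer.shape != population.shape or layer.shape != zones.shape:
        raise ValueError(
            f"shape mismatch: layer {layer.shape}, population "
            f"{population.shape}, zones {zones.shape}"
        )
    if np.any(population.values[population.valid_mask()] < 0):
        raise ValueError("population layer contains negative values")

    valid = layer.valid_mask() & population.valid_mask()
    labels = zones.labels
    out: dict[int, float] = {}
    for region in zones.regions():
        m = (labels == region) & valid
        pop = population.values[m]
        total = pop.sum()
        if total <= 0:
            logger.warning(
                "zone %d has zero valid population; exposure undefined", region
            )
            out[int(region)] = float("nan")
            continue
        w = pop / total
        out[int(region)] = float(np.dot(w, layer.values[m]))
    return out


def exposure_table(
    layers: Mapping[str, GridLayer], population: GridLayer, zones: ZoneMap
) -> pd.DataFrame:
    """Table of population-weighted exposures: one row per region, one
    column per named layer."""
    cols = {
        name: weighted_zonal_mean(layer, population, zones)
        for name, layer in layers.items()
    }
    table = pd.DataFrame(cols)
    table.index.name = "region"
    return table.sort_index()
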