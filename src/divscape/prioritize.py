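"""Conservation prioritization by top-quartile raster intersection.

Priority cells are those simultaneously above the third quartile of
every input layer's cell-value distribution — e.g. habitat suitability
now, suitability under future climate, and a diversity layer (allelic
richness or phenotypic variation). Quartiles are taken over the
empirical distribution of valid cell values with linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .raster import GridRaster

__all__ = ["PriorityMask", "top_quartile_mask", "intersect_priority"]


@dataclass
class PriorityMask:
    """Boolean priority raster with the per-layer quartile cutoffs that built it."""

    grid: GridRaster
    cells: np.ndarray  # boolean, grid shape
    inputs: list[tuple[str, float]]  # (layer name, cutoff value)

    def to_raster(self) -> GridRaster:
        """1/0 raster; cells that are nodata in the geometry template stay nodata."""
        return self.grid.like(self.cells.astype(float))

    @property
    def n_priority(self) -> int:
        return int(self.cells.sum())


def top_quartile_mask(r: GridRaster, quantile: float = 0.75) -> tuple[np.ndarray, float]:
    """Mask of cells strictly above the layer's 75th percentile, plus the cutoff.

    Nodata cells are never selected. A constant layer yields an empty mask
    (with a warning): no cell exceeds the cutoff.
    """
    vals = r.valid_values
    if vals.size < 4:
        raise ValueError("need at least 4 valid cells for a quartile")
    cutoff = float(np.percentile(vals, 100 * quantile))  # linear interpolation
    mask = np.zeros(r.shape, dtype=bool)
    mask[r.valid_mask] = r.values[r.valid_mask] > cutoff
    if not mask.any():
        warnings.warn("constant or degenerate layer: empty top-quartile mask")
    return mask, cutoff


def intersect_priority(
    layers: list[tuple[str, GridRaster]], quantile: float = 0.75
) -> PriorityMask:
    """AND of the top-quartile masks of named layers sharing one geometry."""
    if len(layers) < 2:
        raise ValueError("need at least 2 layers to intersect")
    names, rasters = zip(*layers)
    first = rasters[0]
    for r in rasters[1:]:
        if not first.same_geometry(r):
            raise ValueError("raster geometries do not match")
    combined = np.ones(first.shape, dtype=bool)
    inputs = []
    for name, r in layers:
        mask, cutoff = top_quartile_mask(r, quantile)
        combined &= mask
        inputs.append((name, cutoff))
    return PriorityMask(first.like(), combined, inputs)
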