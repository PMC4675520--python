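"""Stacks of co-registered environmental rasters (bioclim-style layers)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .raster import GridRaster, read_ascii_grid, write_ascii_grid


class EnvStack:
    """An ordered set of environmental layers sharing one grid geometry.

    Layers play the role of bioclimatic predictors: each is a
    :class:`~divscape.raster.GridRaster`, and all must share extent,
    resolution and nodata pattern compatibility.
    """

    def __init__(self, layers: dict[str, GridRaster]):
        if not layers:
            raise ValueError("empty stack")
        names = list(layers)
        first = layers[names[0]]
        for name in names[1:]:
            if not layers[name].same_geometry(first):
                raise ValueError(f"layer {name!r} geometry differs from {names[0]!r}")
        self.names: list[str] = names
        self.layers: dict[str, GridRaster] = dict(layers)

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> GridRaster:
        return self.layers[name]

    @property
    def grid(self) -> GridRaster:
        """A template raster carrying the shared geometry."""
        return self.layers[self.names[0]]

    @property
    def extent(self):
        return self.grid.extent

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        m = np.ones(self.shape, dtype=bool)
        for name in self.names:
            m &= self.layers[name].valid_mask
        return m

    def extract(self, lon, lat) -> pd.DataFrame:
        """Layer values at point locations; rows with any NaN mark failed extraction."""
        data = {name: self.layers[name].sample(lon, lat) for name in self.names}
        return pd.DataFrame(data)

    def cell_table(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid, n_layers) matrix of values at jointly valid cells + flat mask."""
        mask = self.valid_mask()
        cols = [self.layers[name].values[mask] for name in self.names]
        return np.column_stack(cols), mask

    def write_dir(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self.names:
            write_ascii_grid(self.layers[name], directory / f"{name}.asc")

    @classmethod
    def read_dir(cls, directory) -> "EnvStack":
        directory = Path(directory)
        paths = sorted(directory.glob("*.asc"))
        if not paths:
            raise FileNotFoundError(f"no .asc layers found in {directory}")
        return cls({p.stem: read_ascii_grid(p) for p in paths})
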