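"""Readers and writers for the pipeline's tabular formats.

Points travel as CSV (``id, lon, lat, variety[, region, source]``);
genotypes as a GenAlEx-style codominant layout with two integer columns
per locus and 0 encoding a missing call pair; traits as a plain CSV
indexed by individual id. Rasters are handled in :mod:`divscape.raster`
(ESRI ASCII grids).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .popgen import GenotypeTable

__all__ = [
    "read_points",
    "write_points",
    "read_genotypes",
    "write_genotypes",
    "read_traits",
    "write_traits",
]

VARIETIES = {"wild", "cultivated"}


def read_points(path) -> pd.DataFrame:
    """Read and validate a points CSV.

    Required columns: ``id, lon, lat, variety``; optional ``region`` and
    ``source``. Longitude must lie in [-180, 180], latitude in [-90, 90],
    and variety in {wild, cultivated}; a malformed row is reported with
    its line number.
    """
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "lon", "lat", "variety"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"points file lacks columns: {sorted(missing)}")
    for i, rec in df.iterrows():
        line = i + 2  # header is line 1
        try:
            lon, lat = float(rec["lon"]), float(rec["lat"])
        except (TypeError, ValueError):
            raise ValueError(f"line {line}: non-numeric coordinates") from None
        if not (-180 <= lon <= 180):
            raise ValueError(f"line {line}: longitude {lon} outside [-180, 180]")
        if not (-90 <= lat <= 90):
            raise ValueError(f"line {line}: latitude {lat} outside [-90, 90]")
        if rec["variety"] not in VARIETIES:
            raise ValueError(
                f"line {line}: unknown variety {rec['variety']!r} "
                f"(expected one of {sorted(VARIETIES)})"
            )
    if "region" not in df.columns:
        df["region"] = "all"
    if "source" not in df.columns:
        df["source"] = "unknown"
    return df


def write_points(points: pd.DataFrame, path) -> None:
    points.to_csv(path, index=False)


def write_genotypes(table: GenotypeTable, path) -> None:
    """Write genotypes as CSV with two columns per locus (missing = 0)."""
    data: dict[str, object] = {"id": table.ids}
    for j, locus in enumerate(table.loci):
        data[f"{locus}.1"] = table.calls[:, j, 0]
        data[f"{locus}.2"] = table.calls[:, j, 1]
    pd.DataFrame(data).to_csv(path, index=False)


def read_genotypes(path, points: pd.DataFrame) -> GenotypeTable:
    """Read a two-columns-per-locus genotype CSV, attaching coordinates.

    Coordinates come from the points table, matched on id. A call pair
    with exactly one missing allele is treated as wholly missing, with a
    warning.
    """
    df = pd.read_csv(path, dtype={"id": str})
    call_cols = [c for c in df.columns if c != "id"]
    if len(call_cols) % 2 != 0:
        raise ValueError(f"odd number of allele columns ({len(call_cols)})")
    loci = []
    for i in range(0, len(call_cols), 2):
        name = call_cols[i].rsplit(".", 1)[0]
        loci.append(name)
    n, L = len(df), len(loci)
    calls = np.zeros((n, L, 2), dtype=int)
    for j in range(L):
        calls[:, j, 0] = df[call_cols[2 * j]].to_numpy(dtype=int)
        calls[:, j, 1] = df[call_cols[2 * j + 1]].to_numpy(dtype=int)
    half = (calls == 0).sum(axis=2) == 1
    if half.any():
        warnings.warn(
            f"{int(half.sum())} half-missing call pair(s) treated as fully missing"
        )
        calls[half] = 0
    coord_map = points.set_index("id")[["lon", "lat"]]
    try:
        coords = coord_map.loc[df["id"]].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"genotyped individual missing from points table: {exc}") from None
    return GenotypeTable(list(df["id"]), loci, calls, coords)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index_label="id")


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")
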