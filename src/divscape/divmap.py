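"""Grid-based spatial mapping of genetic and phenotypic diversity.

Each georeferenced tree is replicated into every grid cell whose center
falls inside a circular neighborhood (default 2 degrees diameter) around
the tree. Because this replication leaves cells with unequal sample
sizes, cell statistics are computed on bootstrapped subsamples of a
fixed number of trees (default 3, without replacement, 1000 replicates)
— a rarefaction that makes cells comparable; cells below the minimum are
discarded (nodata).

Neighborhood membership is evaluated in flat degree-space (the circle
lives on the lon/lat plane): the diameter is specified in degrees and
the intended study regions straddle the equator, where the distortion
relative to great-circle distance is minimal. Membership uses cell
centers, the simplest testable convention.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .popgen import GenotypeTable, LCACatalog
from .raster import GridRaster, merge_rasters_max, standardize_raster  # noqa: F401 (re-export)

__all__ = [
    "NeighborhoodAssignment",
    "BootstrapSpec",
    "assign_neighborhoods",
    "cell_statistic_bootstrap",
    "make_richness_stat",
    "make_ho_stat",
    "make_lca_richness_stat",
    "make_cv_stat",
    "phenotypic_cv",
    "compare_collection_cvs",
    "standardize_raster",
    "merge_rasters_max",
]


@dataclass
class NeighborhoodAssignment:
    """Cell -> individual-id lists produced by circular-neighborhood replication."""

    grid: GridRaster
    diameter_deg: float
    cells: dict[tuple[int, int], list[str]]

    def occupied(self) -> dict[tuple[int, int], list[str]]:
        return {c: ids for c, ids in self.cells.items() if ids}


@dataclass
class BootstrapSpec:
    """Rarefaction parameters: subsample size, replicate count and RNG seed."""

    sample_size: int = 3
    replicates: int = 1000
    seed: int = 0
    without_replacement: bool = True

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def assign_neighborhoods(
    points: pd.DataFrame, grid: GridRaster, diameter_deg: float = 2.0
) -> NeighborhoodAssignment:
    """Replicate each tree into all cells with centers within ``diameter/2``.

    ``points`` needs columns ``id``, ``lon``, ``lat``. Points outside the
    grid extent are dropped. ``diameter_deg = 0`` degenerates to assigning
    each tree only to its containing cell.
    """
    if diameter_deg <= grid.resolution_deg:
        warnings.warn(
            f"neighborhood diameter {diameter_deg} deg <= cell size "
            f"{grid.resolution_deg:.3f} deg: neighborhoods degenerate to single cells"
        )
    radius = diameter_deg / 2.0
    lon_min, lon_max, lat_min, lat_max = grid.extent
    res = grid.resolution_deg
    nrows, ncols = grid.shape
    clon, clat = grid.cell_centers()
    col_lons = clon[0, :]
    row_lats = clat[:, 0]
    cells: dict[tuple[int, int], list[str]] = {}
    inside = grid.contains(points["lon"].to_numpy(), points["lat"].to_numpy())
    for _, rec in points.loc[inside].iterrows():
        lon, lat = float(rec["lon"]), float(rec["lat"])
        if radius == 0:
            cells.setdefault(grid.cell_of(lon, lat), []).append(rec["id"])
            continue
        c0 = max(0, int(math.floor((lon - radius - lon_min) / res)) - 1)
        c1 = min(ncols, int(math.ceil((lon + radius - lon_min) / res)) + 1)
        r0 = max(0, int(math.floor((lat_max - (lat + radius)) / res)) - 1)
        r1 = min(nrows, int(math.ceil((lat_max - (lat - radius)) / res)) + 1)
        dx = col_lons[c0:c1] - lon
        dy = row_lats[r0:r1] - lat
        within = (dx[None, :] ** 2 + dy[:, None] ** 2) <= radius**2 + 1e-12
        for rr, cc in zip(*np.nonzero(within)):
            cells.setdefault((r0 + int(rr), c0 + int(cc)), []).append(rec["id"])
    return NeighborhoodAssignment(grid, diameter_deg, cells)


def cell_statistic_bootstrap(
    assignment: NeighborhoodAssignment,
    stat,
    spec: BootstrapSpec,
) -> GridRaster:
    """Per-cell mean of a statistic over fixed-size bootstrap subsamples.

    Cells with fewer trees than ``spec.sample_size`` become nodata. A cell
    with exactly ``sample_size`` trees has a single possible subsample, so
    its value is the statistic on the full set. Replicates on which the
    statistic raises are skipped; if more than half of a cell's replicates
    fail the cell is set to nodata.

    Replicate streams are derived per cell from ``spec.seed`` and the cell
    index, so results are reproducible regardless of evaluation order.
    """
    grid = assignment.grid
    out = np.full(grid.shape, np.nan)
    m = spec.sample_size
    for (row, col), ids in assignment.cells.items():
        n = len(ids)
        if n < m:
            continue
        if n == m and spec.without_replacement:
            try:
                out[row, col] = float(stat(list(ids)))
            except Exception:
                pass
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, row, col])
        )
        ids_arr = np.asarray(ids, dtype=object)
        total = 0.0
        ok = 0
        for _ in range(spec.replicates):
            pick = rng.choice(n, size=m, replace=not spec.without_replacement)
            try:
                total += float(stat(list(ids_arr[pick])))
                ok += 1
            except Exception:
                continue
        if ok > spec.replicates / 2:
            out[row, col] = total / ok
    return grid.like(out)


# -- statistic factories ----------------------------------------------------


def _allele_bitmasks(calls: np.ndarray) -> np.ndarray:
    """(n, L) bitmask of the alleles each individual carries at each locus.

    Allele labels are small positive integers, so a locus's allele set fits
    in one machine word; pooling a subsample is a bitwise OR and counting
    distinct alleles a popcount — this keeps the statistic cheap inside the
    bootstrap loop.
    """
    masks = np.zeros(calls.shape[:2], dtype=np.uint64)
    for copy in range(2):
        a = calls[:, :, copy].astype(np.uint64)
        masks |= np.where(a > 0, np.uint64(1) << (a - 1), 0).astype(np.uint64)
    return masks


def make_richness_stat(table: GenotypeTable):
    """Mean number of distinct alleles per scored locus in a subsample."""
    masks = _allele_bitmasks(table.calls)

    def richness(ids) -> float:
        rows = table.rows(ids)
        pooled = np.bitwise_or.reduce(masks[rows], axis=0)
        scored = pooled > 0
        if not scored.any():
            raise ValueError("no scored locus in subsample")
        return float(np.bitwise_count(pooled[scored]).mean())

    return richness


def make_ho_stat(table: GenotypeTable):
    """Mean observed heterozygosity across loci in a subsample."""
    het = (table.calls[:, :, 0] != table.calls[:, :, 1])  # (n, L)
    scored = ~table.missing_mask

    def ho(ids) -> float:
        rows = table.rows(ids)
        n_scored = scored[rows].sum(axis=0)
        use = n_scored > 0
        if not use.any():
            raise ValueError("no scored locus in subsample")
        return float((het[rows].sum(axis=0)[use] / n_scored[use]).mean())

    return ho


def make_lca_richness_stat(table: GenotypeTable, catalog: LCACatalog):
    """Mean number of distinct locally common alleles per scored locus."""
    lca = catalog.lca_set()
    masks = _allele_bitmasks(table.calls)
    locus_lca_mask = np.zeros(len(table.loci), dtype=np.uint64)
    for j, locus in enumerate(table.loci):
        for allele in range(1, 65):
            if (locus, allele) in lca:
                locus_lca_mask[j] |= np.uint64(1) << (allele - 1)

    def lca_richness(ids) -> float:
        rows = table.rows(ids)
        pooled = np.bitwise_or.reduce(masks[rows], axis=0)
        scored = pooled > 0
        if not scored.any():
            raise ValueError("no scored locus in subsample")
        hits = pooled[scored] & locus_lca_mask[scored]
        return float(np.bitwise_count(hits).mean())

    return lca_richness


def phenotypic_cv(traits: pd.DataFrame, subset) -> float:
    """Mean coefficient of variation (sd/mean, sample sd) across traits.

    ``traits`` is indexed by individual id with one numeric column per
    trait. Traits with fewer than two non-missing values in the subset, or
    a zero mean, are excluded; the mean over remaining traits is unweighted.
    """
    sub = traits.loc[list(subset)]
    if len(sub) < 2:
        raise ValueError("subset must contain at least 2 individuals")
    cvs = []
    for col in sub.columns:
        vals = sub[col].dropna().to_numpy(dtype=float)
        if vals.size < 2:
            continue
        mean = vals.mean()
        if mean == 0:
            continue
        cvs.append(vals.std(ddof=1) / mean)
    if not cvs:
        raise ValueError("no usable trait in subset")
    return float(np.mean(cvs))


def make_cv_stat(traits: pd.DataFrame):
    """Phenotypic-variation statistic bound to one trait table.

    Precomputes a dense matrix so the statistic stays cheap inside the
    bootstrap loop; semantics match :func:`phenotypic_cv`.
    """
    values = traits.to_numpy(dtype=float)
    row_of = {i: k for k, i in enumerate(traits.index)}

    def cv(ids) -> float:
        rows = [row_of[i] for i in ids]
        if len(rows) < 2:
            raise ValueError("subset must contain at least 2 individuals")
        sub = values[rows]
        cvs = []
        for col in range(sub.shape[1]):
            vals = sub[:, col]
            vals = vals[~np.isnan(vals)]
            if vals.size < 2 or vals.mean() == 0:
                continue
            cvs.append(vals.std(ddof=1) / vals.mean())
        if not cvs:
            raise ValueError("no usable trait in subset")
        return float(np.mean(cvs))

    return cv


CVComparison = namedtuple("CVComparison", "F p_f t p_t")


def compare_collection_cvs(cv_a, cv_b) -> CVComparison:
    """Fisher's variance-ratio F test and pooled-variance t test on CV lists.

    The F test (two-sided) gates homoscedasticity; the t test then uses
    the pooled variance, mirroring the usual reporting order.
    """
    a = np.asarray(cv_a, dtype=float)
    b = np.asarray(cv_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per collection")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both collections: tests undefined")
    F = va / vb if vb > 0 else np.inf
    dfa, dfb = a.size - 1, b.size - 1
    cdf = sps.f.cdf(F, dfa, dfb)
    p_f = float(2 * min(cdf, 1 - cdf))
    t, p_t = sps.ttest_ind(a, b, equal_var=True)
    return CVComparison(float(F), p_f, float(t), float(p_t))


def exhaustive_cell_mean(ids, stat, sample_size: int) -> float:
    """Exact mean of a statistic over all C(n, m) subsamples of a cell.

    Reference computation for small cells; the bootstrap converges to it.
    """
    vals = [stat(list(combo)) for combo in itertools.combinations(ids, sample_size)]
    return float(np.mean(vals))
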