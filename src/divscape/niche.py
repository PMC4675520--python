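"""Environmental-niche analysis in PCA space.

Occurrence points are projected onto the first two principal components
of the (centered, unit-scaled) environmental predictors extracted at all
presence locations. The realized niche of the wild form is delimited by
the convex hull of its points, dilated outward by a buffer equal to a
fraction (default 3%) of the largest hull axis; cultivated points are
then partitioned into inside/outside that extended hull. Niche overlap
between two point sets is Schoener's D on gridded, Gaussian-smoothed
occurrence densities over the PC plane, with permutation-based
equivalency and similarity tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull
from shapely.geometry import Point, Polygon
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .stack import EnvStack

__all__ = [
    "EnvSpace",
    "NicheHull",
    "NicheDensity",
    "pca_env",
    "build_hull",
    "filter_in_niche",
    "grid_density",
    "schoeners_d",
    "niche_equivalency_test",
    "niche_similarity_test",
]


@dataclass
class EnvSpace:
    """Two-component PCA of the environment at presence points."""

    scores: np.ndarray          # (n_points, 2)
    loadings: np.ndarray        # (n_vars, 2)
    explained: np.ndarray       # fraction of variance per component
    var_names: list[str]
    kept: np.ndarray            # indices of input points with valid extraction


def pca_env(points, env: EnvStack) -> EnvSpace:
    """Project presence points onto the first two environmental PCs.

    ``points`` is a DataFrame with ``lon``/``lat`` columns. Points whose
    extraction fails (outside the grid or over nodata) are excluded;
    constant variables are dropped. Variables are centered and scaled to
    unit variance before the decomposition.
    """
    vals = env.extract(points["lon"].to_numpy(), points["lat"].to_numpy())
    kept = np.nonzero(~vals.isna().any(axis=1).to_numpy())[0]
    if kept.size < 3:
        raise ValueError("need at least 3 points with valid environmental extraction")
    X = vals.to_numpy(dtype=float)[kept]
    keep_var = X.std(axis=0) > 0
    names = [n for n, k in zip(env.names, keep_var) if k]
    if keep_var.sum() < 2:
        raise ValueError("fewer than 2 non-constant environmental variables")
    X = StandardScaler().fit_transform(X[:, keep_var])
    pca = PCA(n_components=2)
    scores = pca.fit_transform(X)
    return EnvSpace(
        scores=scores,
        loadings=pca.components_.T,
        explained=pca.explained_variance_ratio_,
        var_names=names,
        kept=kept,
    )


@dataclass
class NicheHull:
    """Convex hull of wild-form scores, dilated by a fraction of its largest axis."""

    polygon: Polygon
    base_polygon: Polygon
    buffer_fraction: float
    base_axis_length: float


def build_hull(scores: np.ndarray, buffer_fraction: float = 0.03) -> NicheHull:
    """Convex hull of PC scores with an outward buffer.

    The buffer distance is ``buffer_fraction`` times the largest hull axis
    (the maximum pairwise distance between hull vertices); dilation uses
    rounded joins, i.e. a true offset of the polygon boundary.
    """
    pts = np.asarray(scores, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a hull")
    if buffer_fraction < 0:
        raise ValueError("buffer_fraction must be nonnegative")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull rejects degenerate (collinear) input
        raise ValueError("degenerate hull: points are collinear") from exc
    verts = pts[hull.vertices]
    diffs = verts[:, None, :] - verts[None, :, :]
    axis = float(np.sqrt((diffs**2).sum(-1)).max())
    base = Polygon(verts)
    dist = buffer_fraction * axis
    poly = base.buffer(dist, join_style="round") if dist > 0 else base
    return NicheHull(poly, base, buffer_fraction, axis)


def filter_in_niche(hull: NicheHull, scores: np.ndarray):
    """Partition point indices by the buffered hull (boundary counts as inside)."""
    pts = np.atleast_2d(np.asarray(scores, dtype=float))
    inside, outside = [], []
    for i, (x, y) in enumerate(pts):
        (inside if hull.polygon.covers(Point(x, y)) else outside).append(i)
    return np.array(inside, dtype=int), np.array(outside, dtype=int)


@dataclass
class NicheDensity:
    """Normalized, smoothed occurrence density on a fixed PC-space lattice."""

    density: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    bandwidth: tuple[float, float]

    def __post_init__(self) -> None:
        total = self.density.sum()
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"density sums to {total}, expected 1")

    def same_lattice(self, other: "NicheDensity") -> bool:
        return (
            self.density.shape == other.density.shape
            and np.allclose(self.x_edges, other.x_edges)
            and np.allclose(self.y_edges, other.y_edges)
        )


def _silverman(vals: np.ndarray) -> float:
    n = vals.size
    sd = vals.std(ddof=1) if n > 1 else 1.0
    return 1.06 * max(sd, 1e-9) * n ** (-1 / 5)


def grid_density(
    scores: np.ndarray,
    bounds: tuple[float, float, float, float],
    resolution: int = 100,
    bandwidth: tuple[float, float] | None = None,
) -> NicheDensity:
    """Histogram the scores on an R x R lattice and smooth with a Gaussian kernel.

    ``bounds = (xmin, xmax, ymin, ymax)`` fixes the lattice so densities of
    different point sets are comparable. Bandwidth defaults to Silverman's
    rule per axis. The smoothed grid is renormalized to sum to one.
    """
    pts = np.atleast_2d(np.asarray(scores, dtype=float))
    xmin, xmax, ymin, ymax = bounds
    x_edges = np.linspace(xmin, xmax, resolution + 1)
    y_edges = np.linspace(ymin, ymax, resolution + 1)
    hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[x_edges, y_edges])
    if bandwidth is None:
        bandwidth = (_silverman(pts[:, 0]), _silverman(pts[:, 1]))
    dx = (xmax - xmin) / resolution
    dy = (ymax - ymin) / resolution
    sigma = (bandwidth[0] / dx, bandwidth[1] / dy)
    dens = gaussian_filter(hist, sigma=sigma, mode="constant")
    total = dens.sum()
    if total == 0:
        raise ValueError("no points fall inside the lattice bounds")
    return NicheDensity(dens / total, x_edges, y_edges, bandwidth)


def joint_bounds(*score_sets: np.ndarray, pad: float = 0.1) -> tuple[float, float, float, float]:
    """A lattice bounding box covering all score sets, padded proportionally."""
    allpts = np.vstack([np.atleast_2d(s) for s in score_sets])
    xmin, ymin = allpts.min(axis=0)
    xmax, ymax = allpts.max(axis=0)
    px = pad * (xmax - xmin or 1.0)
    py = pad * (ymax - ymin or 1.0)
    return xmin - px, xmax + px, ymin - py, ymax + py


def schoeners_d(a: NicheDensity, b: NicheDensity) -> float:
    """Schoener's D = 1 - 0.5 * sum |a - b|; 0 = no overlap, 1 = complete."""
    if not a.same_lattice(b):
        raise ValueError("densities are on different lattices")
    return float(1.0 - 0.5 * np.abs(a.density - b.density).sum())


def _d_between(scores_a, scores_b, bounds, resolution, bandwidth) -> float:
    da = grid_density(scores_a, bounds, resolution, bandwidth)
    db = grid_density(scores_b, bounds, resolution, bandwidth)
    return schoeners_d(da, db)


def _shared_bandwidth(scores_a, scores_b):
    pooled = np.vstack([np.atleast_2d(scores_a), np.atleast_2d(scores_b)])
    return (_silverman(pooled[:, 0]), _silverman(pooled[:, 1]))


def niche_equivalency_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    permutations: int = 99,
    seed: int | None = None,
    resolution: int = 100,
) -> tuple[float, float]:
    """Niche-equivalency permutation test on Schoener's D.

    The null pools both point sets and re-splits them at the original
    sizes; niches are declared non-equivalent when the observed overlap is
    lower than expected for one pooled niche, so
    ``p = (1 + #{D_null <= D_obs}) / (perms + 1)``.
    """
    a = np.atleast_2d(np.asarray(scores_a, dtype=float))
    b = np.atleast_2d(np.asarray(scores_b, dtype=float))
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 points per set")
    if permutations < 99:
        warnings.warn(
            f"{permutations} permutations give a p-value resolution of only "
            f"{1 / (permutations + 1):.3f}"
        )
    bounds = joint_bounds(a, b)
    bw = _shared_bandwidth(a, b)
    d_obs = _d_between(a, b, bounds, resolution, bw)
    pooled = np.vstack([a, b])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(len(pooled))
        pa, pb = pooled[perm[: len(a)]], pooled[perm[len(a):]]
        if _d_between(pa, pb, bounds, resolution, bw) <= d_obs + 1e-12:
            hits += 1
    return d_obs, (1 + hits) / (permutations + 1)


def niche_similarity_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    background_b: np.ndarray,
    permutations: int = 99,
    seed: int | None = None,
    resolution: int = 100,
) -> tuple[float, float]:
    """Niche-similarity test: is overlap higher than for a randomly placed niche?

    The null relocates set b's point cloud to random centers drawn from
    its available environmental background, preserving its internal shape,
    and recomputes D each time; ``p = (1 + #{D_null >= D_obs}) / (perms + 1)``
    (similarity is declared when the observed overlap is unusually high).
    """
    a = np.atleast_2d(np.asarray(scores_a, dtype=float))
    b = np.atleast_2d(np.asarray(scores_b, dtype=float))
    bg = np.atleast_2d(np.asarray(background_b, dtype=float))
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 points per set")
    if permutations < 99:
        warnings.warn(
            f"{permutations} permutations give a p-value resolution of only "
            f"{1 / (permutations + 1):.3f}"
        )
    bounds = joint_bounds(a, b, bg)
    bw = _shared_bandwidth(a, b)
    d_obs = _d_between(a, b, bounds, resolution, bw)
    centroid = b.mean(axis=0)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        new_center = bg[rng.integers(len(bg))]
        shifted = b - centroid + new_center
        if _d_between(a, shifted, bounds, resolution, bw) >= d_obs - 1e-12:
            hits += 1
    return d_obs, (1 + hits) / (permutations + 1)
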