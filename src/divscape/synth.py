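"""Synthetic landscapes, presence points, SSR genotypes and fruit traits.

This module generates data with the statistical structure the analysis
pipeline assumes, so every downstream stage is testable without any
external download:

* **Environment** — stacks of smooth, mutually correlated (but not
  collinear) gradient-plus-noise layers standing in for bioclimatic
  predictors, plus alternative-climate stacks with shifted gradients.
* **Presences** — wild points drawn proportional to a logistic function
  of the environment and concentrated around circular *refugia*
  (persistence regions); cultivated points from an additively shifted,
  variance-inflated niche, so that some fall outside the wild envelope.
* **Genotypes** — codominant diploid SSR calls whose allele frequencies
  vary smoothly in space (a Gaussian-process logit field per allele,
  length scale ``ibd_scale``), producing isolation by distance; each
  refugium can carry *private* alleles at appreciable local frequency
  and zero frequency elsewhere — the signal the locally-common-allele
  classifier is designed to recover.
* **Traits** — correlated, positive-valued fruit traits with a
  region-dependent coefficient of variation.

Everything is driven by explicit integer seeds: identical seeds yield
bitwise-identical outputs. The allele-frequency field is a spatially
autocorrelated stand-in, not a coalescent simulation — sufficient for
the mapping statistics exercised here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen import GenotypeTable
from .raster import GridRaster
from .stack import EnvStack

__all__ = [
    "Refugium",
    "SyntheticWorld",
    "generate_env",
    "generate_world",
    "generate_presences",
    "generate_genotypes",
    "generate_traits",
]

DEFAULT_EXTENT = (-80.0, -60.0, -10.0, 10.0)  # 20 x 20 degrees on the equator
DEFAULT_RESOLUTION_ARCMIN = 10.0
DEFAULT_N_VARS = 4


@dataclass(frozen=True)
class Refugium:
    """A circular persistence region (degrees)."""

    lon: float
    lat: float
    radius_deg: float
    name: str = "R"


@dataclass
class SyntheticWorld:
    """A synthetic study system: climates plus refugia, all on one grid."""

    env_current: EnvStack
    env_alt: dict[str, EnvStack]
    refugia: list[Refugium]
    seed: int
    suitability_weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lon_min, lon_max, lat_min, lat_max = self.env_current.extent
        for ref in self.refugia:
            if not (lon_min <= ref.lon <= lon_max and lat_min <= ref.lat <= lat_max):
                raise ValueError(f"refugium {ref.name} lies outside the extent")
        for name, stack in self.env_alt.items():
            if not stack.grid.same_geometry(self.env_current.grid):
                raise ValueError(f"alternative climate {name!r} geometry differs")

    @property
    def extent(self):
        return self.env_current.extent

    def true_suitability(self, env: EnvStack | None = None) -> GridRaster:
        """The generating suitability surface (logistic in the env layers)."""
        stack = env or self.env_current
        X, mask = stack.cell_table()
        eta = (X - X.mean(axis=0)) / X.std(axis=0) @ self.suitability_weights
        vals = np.full(stack.shape, np.nan)
        vals[mask] = 1.0 / (1.0 + np.exp(-eta))
        return stack.grid.like(vals)


def _gradient_layer(grid: GridRaster, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """One standardized low-frequency gradient + white noise field."""
    clon, clat = grid.cell_centers()
    lon_min, lon_max, lat_min, lat_max = grid.extent
    u = (clon - lon_min) / (lon_max - lon_min)
    v = (clat - lat_min) / (lat_max - lat_min)
    vals = rng.normal(0, 1) * u + rng.normal(0, 1) * v
    for _ in range(3):
        fx, fy = rng.uniform(0.5, 1.5, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        vals = vals + rng.normal(0, 0.7) * np.cos(2 * np.pi * (fx * u + fy * v) + phase)
    vals = vals + noise_sd * rng.normal(size=grid.shape)
    return (vals - vals.mean()) / vals.std()


def generate_env(
    seed: int,
    n_vars: int = DEFAULT_N_VARS,
    extent=DEFAULT_EXTENT,
    resolution_arcmin: float = DEFAULT_RESOLUTION_ARCMIN,
    noise_sd: float = 0.3,
    max_abs_corr: float = 0.95,
) -> EnvStack:
    """Generate a stack of smooth, non-collinear environmental layers.

    Layers are unitless (standardized); pairwise absolute correlation is
    kept below ``max_abs_corr`` by regenerating offending layers.
    """
    if n_vars < 2:
        raise ValueError("need at least 2 environmental variables")
    grid = GridRaster(extent, resolution_arcmin)  # validates extent/resolution
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    layers: list[np.ndarray] = []
    for _ in range(n_vars):
        for _attempt in range(50):
            cand = _gradient_layer(grid, rng, noise_sd)
            flat = cand.ravel()
            if all(
                abs(np.corrcoef(flat, prev.ravel())[0, 1]) < max_abs_corr
                for prev in layers
            ):
                layers.append(cand)
                break
        else:  # pragma: no cover - practically unreachable
            raise RuntimeError("could not generate a sufficiently independent layer")
    return EnvStack(
        {f"bio{i + 1}": grid.like(vals) for i, vals in enumerate(layers)}
    )


def generate_world(
    seed: int,
    n_vars: int = DEFAULT_N_VARS,
    extent=DEFAULT_EXTENT,
    resolution_arcmin: float = DEFAULT_RESOLUTION_ARCMIN,
    n_refugia: int = 3,
    refugium_radius_deg: float = 1.5,
    n_alt: int = 2,
    alt_shift_sd: float = 0.6,
) -> SyntheticWorld:
    """Build a full synthetic world: current climate, alternatives, refugia."""
    env = generate_env(seed, n_vars, extent, resolution_arcmin)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    lon_min, lon_max, lat_min, lat_max = extent
    margin = refugium_radius_deg + 0.5
    refugia = [
        Refugium(
            float(rng.uniform(lon_min + margin, lon_max - margin)),
            float(rng.uniform(lat_min + margin, lat_max - margin)),
            refugium_radius_deg,
            name=f"R{i + 1}",
        )
        for i in range(n_refugia)
    ]
    grid = env.grid
    clon, clat = grid.cell_centers()
    u = (clon - lon_min) / (lon_max - lon_min)
    v = (clat - lat_min) / (lat_max - lat_min)
    env_alt: dict[str, EnvStack] = {}
    for a in range(n_alt):
        shifted = {}
        for name in env.names:
            c0, c1, c2 = rng.normal(0, alt_shift_sd, size=3)
            shifted[name] = grid.like(env[name].values + c0 + c1 * u + c2 * v)
        env_alt[f"alt{a + 1}"] = EnvStack(shifted)
    weights = rng.normal(0, 1.2, size=n_vars)
    return SyntheticWorld(env, env_alt, refugia, seed, weights)


def _refugium_kernel(lon, lat, refugia, scale: float = 1.5) -> np.ndarray:
    """Gaussian proximity to the nearest refugium center (flat degrees)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    d2 = np.min(
        [
            (lon - r.lon) ** 2 + (lat - r.lat) ** 2
            for r in refugia
        ],
        axis=0,
    )
    return np.exp(-d2 / (2.0 * scale**2))


def generate_presences(
    world: SyntheticWorld,
    n_wild: int = 55,
    n_cult: int = 166,
    niche_shift: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw georeferenced wild and cultivated presence points.

    Wild points follow ``sigmoid(w . env) x refugium-proximity`` weights;
    cultivated points use an environment optimum shifted by
    ``niche_shift`` (in standardized env units), a variance-inflated
    (flattened) response, and a relaxed refugium pull, so their niche is
    broader and partly outside the wild envelope. ``niche_shift = 0``
    makes both forms draws from the identical distribution.
    """
    if n_wild <= 0 or n_cult <= 0:
        raise ValueError("n_wild and n_cult must be positive")
    if niche_shift < 0:
        raise ValueError("niche_shift must be nonnegative")
    rng = np.random.default_rng(
        np.random.SeedSequence([world.seed if seed is None else seed, 303])
    )
    env = world.env_current
    grid = env.grid
    X, mask = env.cell_table()
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    eta = Z @ world.suitability_weights
    clon, clat = grid.cell_centers()
    lon_v, lat_v = clon[mask], clat[mask]
    kern = _refugium_kernel(lon_v, lat_v, world.refugia)

    w_wild = (1.0 / (1.0 + np.exp(-eta))) * kern
    # cultivated: optimum shifted by niche_shift standard deviations of the
    # suitability index (the "env units" of the shift), refugium pull relaxed
    # so the occupied niche broadens beyond the wild envelope
    inflate = 1.0 + niche_shift
    shift = niche_shift * eta.std()
    w_cult = (1.0 / (1.0 + np.exp(-(eta - shift)))) * kern ** (1.0 / inflate)

    res = grid.resolution_deg

    def draw(n, weights, prefix, variety):
        p = weights / weights.sum()
        cells = rng.choice(weights.size, size=n, replace=True, p=p)
        jitter = rng.uniform(-res / 2, res / 2, size=(n, 2))
        lons = lon_v[cells] + jitter[:, 0]
        lats = lat_v[cells] + jitter[:, 1]
        regions = [
            world.refugia[
                int(np.argmin([(lo - r.lon) ** 2 + (la - r.lat) ** 2 for r in world.refugia]))
            ].name
            for lo, la in zip(lons, lats)
        ]
        return pd.DataFrame(
            {
                "id": [f"{prefix}{i + 1:03d}" for i in range(n)],
                "lon": lons,
                "lat": lats,
                "variety": variety,
                "region": regions,
                "source": "synthetic",
            }
        )

    wild = draw(n_wild, w_wild, "W", "wild")
    cult = draw(n_cult, w_cult, "C", "cultivated")
    return pd.concat([wild, cult], ignore_index=True)


def _gp_cholesky(coords: np.ndarray, scale: float) -> np.ndarray | None:
    """Cholesky factor of a squared-exponential covariance; None if scale is inf."""
    if np.isinf(scale):
        return None
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-d2 / (2.0 * scale**2)) + 1e-8 * np.eye(coords.shape[0])
    return np.linalg.cholesky(cov)


def _gp_field(chol: np.ndarray | None, n: int, rng: np.random.Generator) -> np.ndarray:
    """One zero-mean GP realization (perfectly correlated when chol is None)."""
    if chol is None:
        return np.full(n, rng.normal())  # infinite length scale: one shared value
    return chol @ rng.normal(size=n)


def generate_genotypes(
    points: pd.DataFrame,
    n_loci: int = 9,
    alleles_per_locus: tuple[int, int] = (4, 12),
    private_allele_rate: float = 0.6,
    ibd_scale: float = 5.0,
    refugia: list[Refugium] | None = None,
    private_freq: float = 0.35,
    refugium_evenness: float = 0.5,
    missing_rate: float = 0.02,
    seed: int = 0,
) -> GenotypeTable:
    """Generate diploid SSR genotypes with IBD and refugium-private alleles.

    Per locus, a global allele pool of size drawn from
    ``alleles_per_locus`` is shared by all individuals; local allele
    frequencies are a softmax of smooth spatial fields with length scale
    ``ibd_scale`` (degrees), which makes genetic similarity decay with
    geographic distance. With probability ``private_allele_rate`` a
    (locus, refugium) pair reserves one allele that occurs at frequency
    ``private_freq`` inside that refugium and zero outside. Refugia are
    also the implanted high-diversity regions: local frequencies there
    are mixed toward uniform with weight ``refugium_evenness``, raising
    allelic richness inside them. Calls are drawn in local Hardy-Weinberg
    proportions; a small fraction of pairs is masked as missing.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    lo, hi = alleles_per_locus
    if lo < 2 or hi > 20 or lo > hi:
        raise ValueError("allele range must lie within [2, 20]")
    if points[["lon", "lat"]].isna().any().any():
        raise ValueError("points without coordinates are not allowed")
    refugia = refugia or []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    coords = points[["lon", "lat"]].to_numpy(dtype=float)
    n = len(points)
    in_refugium = {
        r.name: ((coords[:, 0] - r.lon) ** 2 + (coords[:, 1] - r.lat) ** 2)
        <= r.radius_deg**2
        for r in refugia
    }
    n_private_max = max(0, lo - 3)  # keep >= 3 cosmopolitan alleles per locus
    chol = _gp_cholesky(coords, ibd_scale)
    calls = np.zeros((n, n_loci, 2), dtype=int)
    loci = [f"L{j + 1:02d}" for j in range(n_loci)]
    for j in range(n_loci):
        k = int(rng.integers(lo, hi + 1))
        private: dict[int, np.ndarray] = {}  # allele index -> member mask
        if private_allele_rate > 0 and refugia:
            candidates = [r for r in refugia if rng.random() < private_allele_rate]
            for idx, r in enumerate(candidates[:n_private_max]):
                private[k - 1 - idx] = in_refugium[r.name]
        common = [a for a in range(k) if a not in private]
        base = rng.dirichlet(np.full(len(common), 5.0))
        base = (base + 0.05) / (base + 0.05).sum()  # frequency floor: all alleles drawable
        fields = np.stack(
            [_gp_field(chol, n, rng) for _ in range(len(common))], axis=1
        )
        logits = np.log(base)[None, :] + fields
        freqs_common = np.exp(logits - logits.max(axis=1, keepdims=True))
        freqs_common /= freqs_common.sum(axis=1, keepdims=True)
        freqs = np.zeros((n, k))
        freqs[:, common] = freqs_common
        if refugium_evenness > 0 and refugia:
            any_refugium = np.zeros(n, dtype=bool)
            for members in in_refugium.values():
                any_refugium |= members
            even = np.zeros(k)
            even[common] = 1.0 / len(common)
            freqs[any_refugium] = (
                (1 - refugium_evenness) * freqs[any_refugium]
                + refugium_evenness * even[None, :]
            )
        for a_idx, members in private.items():
            freqs[members, :] *= 1.0 - private_freq
            freqs[members, a_idx] = private_freq
        cum = np.cumsum(freqs, axis=1)
        for copy in range(2):
            u = rng.random(n)
            calls[:, j, copy] = 1 + (u[:, None] > cum[:, :-1]).sum(axis=1)
    if missing_rate > 0:
        miss = rng.random((n, n_loci)) < missing_rate
        calls[miss] = 0
    return GenotypeTable(list(points["id"]), loci, calls, coords)


def generate_traits(
    points: pd.DataFrame,
    n_traits: int = 12,
    cv_by_region: dict[str, float] | None = None,
    trait_means: np.ndarray | None = None,
    factor_loading: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate correlated positive fruit traits with region-dependent CV.

    Each individual carries one latent factor shared across traits
    (loading ``factor_loading``), giving realistic inter-trait
    correlation; trait values are ``mean x (1 + cv_region x z)`` so the
    realized coefficient of variation per region matches the request.
    """
    if n_traits < 2:
        raise ValueError("need at least 2 traits")
    regions = points["region"].astype(str)
    cv_by_region = cv_by_region or {r: 0.2 for r in regions.unique()}
    if any(cv <= 0 for cv in cv_by_region.values()):
        raise ValueError("coefficients of variation must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    if trait_means is None:
        trait_means = rng.uniform(5.0, 100.0, size=n_traits)
    trait_means = np.asarray(trait_means, dtype=float)
    if np.any(trait_means <= 0):
        raise ValueError("trait means must be positive (CV undefined otherwise)")
    if trait_means.size != n_traits:
        raise ValueError("trait_means length must equal n_traits")
    n = len(points)
    lam = factor_loading
    factor = rng.normal(size=n)
    noise = rng.normal(size=(n, n_traits))
    z = lam * factor[:, None] + np.sqrt(1 - lam**2) * noise
    cvs = regions.map(cv_by_region).to_numpy(dtype=float)
    values = trait_means[None, :] * (1.0 + cvs[:, None] * z)
    cols = [f"trait{t + 1:02d}" for t in range(n_traits)]
    return pd.DataFrame(values, index=pd.Index(points["id"], name="id"), columns=cols)
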