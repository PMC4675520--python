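"""Pipeline configuration: every tunable constant in one place."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    """All pipeline constants, with their standard defaults.

    The defaults reproduce the analysis conditions the pipeline is built
    around: a 10 arc-minute grid, 2-degree circular neighborhoods,
    bootstrap subsamples of 3 trees x 1000 replicates, a 5%/25% locally-
    common-allele definition, a 3% hull buffer, 5-fold x 2-repeat cAUC
    evaluation at alpha 0.05, and third-quartile prioritization.
    """

    seed: int = 0
    # grid / neighborhoods
    resolution_arcmin: float = 10.0
    neighborhood_diameter_deg: float = 2.0
    sample_size: int = 3
    replicates: int = 1000
    # locally common alleles
    lca_freq: float = 0.05
    lca_area: float = 0.25
    # niche
    hull_buffer: float = 0.03
    density_resolution: int = 100
    niche_permutations: int = 99
    # sdm
    k_folds: int = 5
    cv_repeats: int = 2
    alpha: float = 0.05
    ssb_tolerance: float = 0.33
    background_factor: int = 10
    background_cap: int = 10000
    # prioritization
    quartile: float = 0.75
    # synthetic world
    extent: tuple[float, float, float, float] = (-80.0, -60.0, -10.0, 10.0)
    n_env_vars: int = 4
    n_refugia: int = 3
    refugium_radius_deg: float = 1.5
    n_alt_climates: int = 2
    n_wild: int = 55
    n_cult: int = 166
    n_cult_genotyped: int = 80
    niche_shift: float = 1.0
    n_loci: int = 9
    alleles_min: int = 4
    alleles_max: int = 12
    private_allele_rate: float = 0.6
    ibd_scale_deg: float = 5.0
    n_traits: int = 12

    def __post_init__(self) -> None:
        for name in ("lca_freq", "lca_area", "hull_buffer", "alpha", "quartile"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in (
            "sample_size", "replicates", "k_folds", "cv_repeats",
            "n_env_vars", "n_loci", "n_wild", "n_cult",
        ):
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v}")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "extent" in data:
            data["extent"] = tuple(data["extent"])
        return cls(**data)

    def to_toml(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                lines.append(f"{f.name} = [{', '.join(repr(x) for x in v)}]")
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            else:
                lines.append(f"{f.name} = {v!r}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
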