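import numpy as np
import pandas as pd
import pytest

from divscape import synth
from divscape.popgen import (
    allele_frequencies,
    allele_sharing_distance,
    classify_lca,
    geographic_distance_matrix,
    mantel_test,
)
from divscape.divmap import compare_collection_cvs


class TestGenerateEnv:
    def test_shape_forced_by_extent_and_resolution(self):
        env = synth.generate_env(1, n_vars=4, extent=(-80, -60, -10, 10),
                                 resolution_arcmin=10.0)
        assert len(env) == 4
        assert env.shape == (120, 120)

    def test_seeded_determinism_bitwise(self):
        a = synth.generate_env(7, 3, (-75, -65, -5, 5), 30.0)
        b = synth.generate_env(7, 3, (-75, -65, -5, 5), 30.0)
        for name in a.names:
            assert np.array_equal(a[name].values, b[name].values)

    def test_single_variable_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_env(1, n_vars=1)

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            synth.generate_env(1, 2, extent=(-60, -60, -10, 10))

    def test_layers_not_collinear(self):
        env = synth.generate_env(3, 5, (-75, -65, -5, 5), 30.0)
        flats = [env[n].values.ravel() for n in env.names]
        for i in range(len(flats)):
            for j in range(i + 1, len(flats)):
                assert abs(np.corrcoef(flats[i], flats[j])[0, 1]) < 0.95


class TestGeneratePresences:
    def test_counts_and_schema(self, small_world):
        pts = synth.generate_presences(small_world, 55, 166)
        assert len(pts) == 221
        assert (pts["variety"] == "wild").sum() == 55
        assert (pts["variety"] == "cultivated").sum() == 166
        assert set(pts.columns) >= {"id", "lon", "lat", "variety", "region", "source"}
        lon_min, lon_max, lat_min, lat_max = small_world.extent
        assert pts["lon"].between(lon_min, lon_max).all()
        assert pts["lat"].between(lat_min, lat_max).all()

    def test_fixed_seed_reproducible(self, small_world):
        a = synth.generate_presences(small_world, 20, 30, seed=5)
        b = synth.generate_presences(small_world, 20, 30, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_shift_gives_identical_distributions(self, small_world):
        """With niche_shift=0 wild and cultivated come from one distribution:
        their mean environmental suitability should be statistically equal."""
        suit = small_world.true_suitability()
        samples = []
        for seed in range(6):
            pts = synth.generate_presences(small_world, 150, 150, niche_shift=0.0,
                                           seed=seed)
            s = suit.sample(pts["lon"].to_numpy(), pts["lat"].to_numpy())
            w = s[(pts["variety"] == "wild").to_numpy()]
            c = s[(pts["variety"] == "cultivated").to_numpy()]
            samples.append(np.nanmean(w) - np.nanmean(c))
        # mean difference fluctuates around zero across seeds
        assert abs(np.mean(samples)) < 0.02

    def test_shift_pushes_cultivated_beyond_wild_envelope(self, small_world):
        """A shifted cultivated niche leaves more points outside the wild
        convex hull in environmental space than an unshifted one."""
        from divscape.niche import build_hull, filter_in_niche, pca_env

        def frac_outside(shift):
            fracs = []
            for seed in range(3):
                pts = synth.generate_presences(small_world, 80, 80,
                                               niche_shift=shift, seed=seed)
                space = pca_env(pts, small_world.env_current)
                kept = pts.iloc[space.kept]
                wild = space.scores[(kept["variety"] == "wild").to_numpy()]
                cult = space.scores[(kept["variety"] == "cultivated").to_numpy()]
                hull = build_hull(wild, 0.03)
                _, outside = filter_in_niche(hull, cult)
                fracs.append(outside.size / len(cult))
            return np.mean(fracs)

        assert frac_outside(2.0) > frac_outside(0.0)

    def test_negative_shift_rejected(self, small_world):
        with pytest.raises(ValueError):
            synth.generate_presences(small_world, 10, 10, niche_shift=-0.5)


class TestGenerateGenotypes:
    def test_allele_counts_in_requested_range(self, small_genotypes):
        freqs = allele_frequencies(small_genotypes)
        for locus, f in freqs.items():
            assert 4 <= len(f) <= 12, locus

    def test_seeded_determinism(self, small_world, small_points):
        a = synth.generate_genotypes(small_points, refugia=small_world.refugia, seed=2)
        b = synth.generate_genotypes(small_points, refugia=small_world.refugia, seed=2)
        assert np.array_equal(a.calls, b.calls)

    def test_zero_private_rate_leaves_no_refugium_restricted_allele(self, small_world, small_points):
        table = synth.generate_genotypes(
            small_points, private_allele_rate=0.0,
            refugia=small_world.refugia, ibd_scale=np.inf, seed=3,
        )
        # with no private alleles and no spatial structure, every allele should
        # be observed both inside and outside each refugium (sampling allowing)
        coords = table.coords
        for r in small_world.refugia:
            inside = ((coords[:, 0] - r.lon) ** 2 + (coords[:, 1] - r.lat) ** 2) <= r.radius_deg**2
            if inside.sum() < 10:
                continue
            for j in range(len(table.loci)):
                copies_in = table.calls[inside, j, :]
                copies_out = table.calls[~inside, j, :]
                only_inside = set(copies_in[copies_in > 0].tolist()) - set(
                    copies_out[copies_out > 0].tolist()
                )
                # alleles seen only inside must be rare chance events, not implants
                for a in only_inside:
                    freq_in = (copies_in == a).sum() / (copies_in > 0).sum()
                    assert freq_in < 0.05

    def test_implanted_private_alleles_recovered_as_lca(self, small_world, small_points, small_genotypes, unit_grid):
        """Refugium-private alleles satisfy the LCA definition on a coarse grid."""
        table = small_genotypes
        grid = small_world.env_current.grid
        cells = {}
        for i, ind in enumerate(table.ids):
            rc = grid.cell_of(table.coords[i, 0], table.coords[i, 1])
            block = (rc[0] // 6, rc[1] // 6)  # 3-degree blocks
            cells.setdefault(block, []).append(ind)
        cat = classify_lca(table, cells, 0.05, 0.25)
        assert len(cat.lca_set()) > 0

    def test_infinite_ibd_scale_no_spatial_signal(self, small_world, small_points):
        """With ibd_scale -> inf, Mantel r is indistinguishable from zero."""
        table = synth.generate_genotypes(
            small_points, private_allele_rate=0.0, ibd_scale=np.inf,
            refugia=small_world.refugia, seed=4,
        )
        geo = geographic_distance_matrix(table)
        gen = allele_sharing_distance(table)
        r, p = mantel_test(geo, gen, permutations=999, seed=0)
        assert p > 0.05

    def test_finite_ibd_scale_positive_mantel(self, small_genotypes):
        geo = geographic_distance_matrix(small_genotypes)
        gen = allele_sharing_distance(small_genotypes)
        r, p = mantel_test(geo, gen, permutations=999, seed=0)
        assert r > 0
        assert p < 0.05

    def test_points_without_coordinates_rejected(self, small_points):
        broken = small_points.copy()
        broken.loc[0, "lon"] = np.nan
        with pytest.raises(ValueError, match="coordinates"):
            synth.generate_genotypes(broken, seed=1)


class TestGenerateTraits:
    def test_realized_cv_matches_request(self, small_points):
        pts = small_points.copy()
        pts["region"] = "A"
        traits = synth.generate_traits(pts, n_traits=10,
                                       cv_by_region={"A": 0.1}, seed=6)
        cvs = traits.std(ddof=1) / traits.mean()
        assert ((cvs > 0.08) & (cvs < 0.12)).mean() > 0.8
        assert cvs.mean() == pytest.approx(0.1, rel=0.2)

    def test_single_trait_rejected(self, small_points):
        with pytest.raises(ValueError):
            synth.generate_traits(small_points, n_traits=1)

    def test_nonpositive_means_rejected(self, small_points):
        with pytest.raises(ValueError, match="positive"):
            synth.generate_traits(
                small_points, n_traits=3, trait_means=np.array([1.0, -2.0, 3.0]), seed=0
            )

    def test_equal_cv_specs_pass_f_test(self, small_points):
        """Two regions with the same CV spec: Fisher's F test on per-trait CVs
        is non-significant in at least 90% of seeds."""
        pts = small_points.copy()
        half = len(pts) // 2
        pts["region"] = ["A"] * half + ["B"] * (len(pts) - half)
        nonsig = 0
        n_seeds = 100
        for seed in range(n_seeds):
            traits = synth.generate_traits(
                pts, n_traits=12, cv_by_region={"A": 0.2, "B": 0.2}, seed=seed
            )
            ta = traits.loc[pts.loc[pts["region"] == "A", "id"]]
            tb = traits.loc[pts.loc[pts["region"] == "B", "id"]]
            cv_a = (ta.std(ddof=1) / ta.mean()).to_numpy()
            cv_b = (tb.std(ddof=1) / tb.mean()).to_numpy()
            res = compare_collection_cvs(cv_a, cv_b)
            nonsig += res.p_f > 0.05
        assert nonsig >= 0.9 * n_seeds

    def test_traits_are_correlated(self, small_points):
        traits = synth.generate_traits(small_points, n_traits=8, seed=9)
        corr = traits.corr().to_numpy()
        off = corr[np.triu_indices(8, k=1)]
        assert off.mean() > 0.1  # shared latent factor induces correlation
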