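import numpy as np
import pandas as pd
import pytest

from divscape import sdm, synth
from divscape.geo import haversine_km
from divscape.raster import GridRaster
from divscape.sdm import (
    EnsembleModel,
    EnsembleSDM,
    EnvelopeModel,
    GeographicNullModel,
    RegressionModel,
    auc,
    best_ensemble,
    cross_validate,
    remove_ssb,
    retain_models,
    sample_background,
    ssb_ratio,
    summarize_scenarios,
    threshold_max_ss,
)


def pts(lon, lat):
    return pd.DataFrame({"lon": np.atleast_1d(lon), "lat": np.atleast_1d(lat)})


class TestSampleBackground:
    def setup_method(self):
        self.region = GridRaster((0.0, 2.0, 0.0, 2.0), 30.0, np.ones((4, 4)))

    def test_all_cells_when_n_equals_count(self):
        bg = sample_background(self.region, 16, seed=0)
        assert len(bg) == 16
        assert len(bg.drop_duplicates()) == 16

    def test_seeded_determinism(self):
        a = sample_background(self.region, 5, seed=3)
        b = sample_background(self.region, 5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_and_overflow(self):
        assert len(sample_background(self.region, 0, seed=0)) == 0
        with pytest.raises(ValueError):
            sample_background(self.region, 17, seed=0)


class TestEnvelopeModel:
    def test_median_scores_one_outside_scores_zero(self):
        pres = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0],
                             "y": [10.0, 20.0, 30.0, 40.0, 50.0]})
        m = EnvelopeModel(pres)
        assert m.score_env(pd.DataFrame({"x": [3.0], "y": [30.0]}))[0] == pytest.approx(1.0)
        assert m.score_env(pd.DataFrame({"x": [9.0], "y": [30.0]}))[0] == 0.0
        assert m.score_env(pd.DataFrame({"x": [3.0], "y": [-1.0]}))[0] == 0.0

    def test_matches_hand_cdf(self):
        """5 presences at x = 1..5: mid-rank CDF at x=2 is 0.3 -> score 0.6."""
        pres = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0],
                             "y": [0.0, 1.0, 2.0, 3.0, 4.0]})
        m = EnvelopeModel(pres)
        q = pd.DataFrame({"x": [2.0], "y": [2.0]})
        assert m.score_env(q)[0] == pytest.approx(min(2 * 0.3, 1.0))

    def test_constant_variable_dropped(self):
        pres = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0], "c": [7.0] * 5})
        m = EnvelopeModel(pres)
        assert "c" not in m.sorted_vals

    def test_too_few_presences_rejected(self):
        with pytest.raises(ValueError):
            EnvelopeModel(pd.DataFrame({"x": [1.0, 2.0]}))


class TestRegressionModel:
    @staticmethod
    def coefficient_z_scores(seed, n=2000, betas=(-0.5, 1.2, -0.8)):
        """Fit on data with known generating coefficients; return (est-truth)/SE."""
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        beta0, beta1, beta2 = betas
        eta = beta0 + beta1 * x + beta2 * x**2
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        pres = pd.DataFrame({"x": x[y]})
        bg = pd.DataFrame({"x": x[~y]})
        m = RegressionModel(pres, bg)
        D = m._design(pd.concat([pres, bg], ignore_index=True))
        yy = np.r_[np.ones(len(pres)), np.zeros(len(bg))]
        ref = sm.Logit(yy, D).fit(disp=0)
        # express the truth on the model's standardized scale
        mu, s = m.means["x"], m.scales["x"]
        truth = np.array(
            [beta0 + beta1 * mu + beta2 * mu**2,
             (beta1 + 2 * beta2 * mu) * s,
             beta2 * s**2]
        )
        return (m.coef - truth) / ref.bse

    def test_recovers_generating_coefficients(self):
        """n=2000 logistic data: each coefficient lies within 2 SE of the
        truth at the expected ~95% per-seed rate."""
        zs = np.array([self.coefficient_z_scores(seed) for seed in range(10)])
        coverage = (np.abs(zs) < 2).mean(axis=0)
        assert np.all(coverage >= 0.7)
        assert np.all(np.abs(zs.mean(axis=0)) < 1.0)  # no gross bias

    def test_background_equal_to_presences_gives_auc_half(self):
        """Identical presence and background points: every score ties -> 0.5."""
        rng = np.random.default_rng(1)
        pres = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
        m = RegressionModel(pres, pres.copy())
        assert auc(m.score_env(pres), m.score_env(pres)) == pytest.approx(0.5)

    def test_constant_variable_dropped(self):
        rng = np.random.default_rng(2)
        pres = pd.DataFrame({"x": rng.normal(1, 1, 50), "c": np.ones(50)})
        bg = pd.DataFrame({"x": rng.normal(-1, 1, 50), "c": np.ones(50)})
        m = RegressionModel(pres, bg)
        assert m.columns == ["x"]


class TestGeographicNull:
    def test_score_one_at_presence(self):
        m = GeographicNullModel([10.0], [0.0])
        assert m.score([10.0], [0.0])[0] == pytest.approx(1.0)

    def test_matches_hand_haversine(self):
        """3-presence toy: scores equal 1/(1+d) with d from a hand formula."""
        plon, plat = [0.0, 5.0, -3.0], [0.0, 2.0, -4.0]
        m = GeographicNullModel(plon, plat)
        qlon, qlat = 1.0, 1.0
        dists = [haversine_km(qlon, qlat, a, b) for a, b in zip(plon, plat)]
        assert m.score([qlon], [qlat])[0] == pytest.approx(1 / (1 + min(dists)))

    def test_ranking_monotone_in_distance(self):
        m = GeographicNullModel([0.0], [0.0])
        s = m.score([1.0, 2.0, 5.0], [0.0, 0.0, 0.0])
        assert s[0] > s[1] > s[2]

    def test_empty_presences_rejected(self):
        with pytest.raises(ValueError):
            GeographicNullModel([], [])


class TestRemoveSSB:
    def test_same_distribution_mostly_matched_ratio_near_one(self):
        rng = np.random.default_rng(0)
        train = pts(rng.uniform(0, 10, 50), rng.uniform(0, 10, 50))
        test_p = pts(rng.uniform(0, 10, 40), rng.uniform(0, 10, 40))
        test_a = pts(rng.uniform(0, 10, 400), rng.uniform(0, 10, 400))
        pi, ai = remove_ssb(test_p, test_a, train)
        assert pi.size >= 0.8 * len(test_p)
        ratio = ssb_ratio(test_p.iloc[pi], test_a.iloc[ai], train)
        assert 0.8 <= ratio <= 1.25

    def test_biased_configuration_leaves_presences_unmatched(self):
        train = pts([0.0], [0.0])
        test_p = pts(np.full(10, 0.01), np.full(10, 0.01))  # all near training
        test_a = pts(np.full(10, 40.0), np.full(10, 40.0))  # all far away
        with pytest.warns(UserWarning, match="unreliable"):
            pi, _ = remove_ssb(test_p, test_a, train)
        assert pi.size == 0

    def test_infinite_tolerance_matches_everything(self):
        rng = np.random.default_rng(1)
        train = pts(rng.uniform(0, 10, 20), rng.uniform(0, 10, 20))
        test_p = pts(rng.uniform(0, 10, 15), rng.uniform(0, 10, 15))
        test_a = pts(rng.uniform(0, 10, 30), rng.uniform(0, 10, 30))
        pi, ai = remove_ssb(test_p, test_a, train, tolerance=np.inf)
        assert pi.size == len(test_p)
        assert len(set(ai)) == len(ai)  # absences used at most once

    def test_matching_never_worsens_ssb(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            train = pts(rng.uniform(0, 10, 30), rng.uniform(0, 10, 30))
            # presences biased toward training points, absences uniform
            base = train.sample(20, random_state=seed, replace=True)
            test_p = pts(base["lon"].to_numpy() + rng.normal(0, 0.5, 20),
                         base["lat"].to_numpy() + rng.normal(0, 0.5, 20))
            test_a = pts(rng.uniform(0, 10, 200), rng.uniform(0, 10, 200))
            before = abs(np.log(ssb_ratio(test_p, test_a, train)))
            pi, ai = remove_ssb(test_p, test_a, train)
            if pi.size == 0:
                continue
            after = abs(np.log(ssb_ratio(test_p.iloc[pi], test_a.iloc[ai], train)))
            assert after <= before + 1e-9


class TestAUC:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([0.9, 0.8], [0.1, 0.2], 1.0),
            ([0.5, 0.5], [0.5, 0.5], 0.5),
            ([0.9, 0.4], [0.5, 0.1], 0.75),
        ],
    )
    def test_values(self, pos, neg, expected):
        assert auc(pos, neg) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.choice([0.1, 0.3, 0.5, 0.7], size=rng.integers(2, 20))
        neg = rng.choice([0.1, 0.3, 0.5, 0.7], size=rng.integers(2, 20))
        total = 0.0
        for p in pos:
            for n in neg:
                total += 1.0 if p > n else (0.5 if p == n else 0.0)
        assert auc(pos, neg) == pytest.approx(total / (len(pos) * len(neg)))


@pytest.fixture(scope="module")
def flat_env():
    """A small environment stack for evaluation-protocol tests."""
    return synth.generate_env(2, 3, (-75.0, -65.0, -5.0, 5.0), 30.0)


def uniform_points(n, seed, extent=(-75.0, -65.0, -5.0, 5.0)):
    rng = np.random.default_rng(seed)
    return pts(rng.uniform(extent[0], extent[1], n), rng.uniform(extent[2], extent[3], n))


class TestCrossValidate:
    def test_null_cauc_near_half_on_unbiased_data(self, flat_env):
        evals = cross_validate(
            {"null": "null"}, uniform_points(100, 0), uniform_points(1000, 1),
            flat_env, seed=0,
        )
        assert evals["null"].cauc_values.size == 10
        assert abs(evals["null"].mean_cauc - 0.5) <= 0.05

    def test_true_model_beats_null(self, small_world, flat_env):
        """A model scoring by the generating suitability out-ranks the null."""
        suit = small_world.true_suitability()

        class Oracle(sdm.SuitabilityModel):
            def score(self, lon, lat, env):
                return np.nan_to_num(suit.sample(lon, lat), nan=0.0)

        pres = synth.generate_presences(small_world, 60, 60, seed=3)
        pres = pres[pres["variety"] == "wild"].reset_index(drop=True)
        bg = uniform_points(600, 4)
        evals = cross_validate(
            {"oracle": lambda p, b, e: Oracle(), "null": "null"},
            pres, bg, small_world.env_current, seed=5,
        )
        assert evals["oracle"].mean_cauc > evals["null"].mean_cauc

    def test_same_seed_identical_results(self, flat_env):
        kw = dict(presences=uniform_points(50, 7), background=uniform_points(200, 8),
                  env=flat_env, seed=9)
        a = cross_validate({"null": "null"}, **kw)
        b = cross_validate({"null": "null"}, **kw)
        assert np.array_equal(a["null"].cauc_values, b["null"].cauc_values)


class TestRetainModels:
    def ev(self, name, vals):
        return sdm.EvaluationSet(name, np.asarray(vals, dtype=float))

    def test_clearly_better_model_retained_with_exact_min_p(self):
        null = self.ev("null", [0.5] * 10)
        good = self.ev("m", [1.0] * 10)
        assert retain_models({"m": good}, null) == ["m"]
        from scipy.stats import mannwhitneyu

        _, p = mannwhitneyu(good.cauc_values, null.cauc_values, alternative="greater")
        # exact one-sided minimum for n=m=10 without the tie path
        assert p < 0.05

    def test_identical_to_null_not_retained(self):
        null = self.ev("null", np.linspace(0.4, 0.6, 10))
        clone = self.ev("m", np.linspace(0.4, 0.6, 10))
        assert retain_models({"m": clone}, null) == []

    def test_alpha_zero_retains_nothing(self):
        null = self.ev("null", [0.5] * 10)
        good = self.ev("m", [1.0] * 10)
        assert retain_models({"m": good}, null, alpha=0.0) == []


class TestEnsemble:
    def test_weights_renormalized_and_convex(self):
        class Const(sdm.SuitabilityModel):
            def __init__(self, v):
                self.v = v

            def score(self, lon, lat, env=None):
                return np.full(np.atleast_1d(lon).shape, self.v)

        ens = EnsembleModel(["a", "b"], np.array([0.6, 0.6]), [Const(0.2), Const(0.8)])
        assert np.allclose(ens.weights, [0.5, 0.5])
        s = ens.score([0.0], [0.0], None)
        assert s[0] == pytest.approx(0.5)  # arithmetic mean at equal weights
        assert 0.2 <= s[0] <= 0.8  # convex combination bound

    def test_single_retained_model_is_the_ensemble(self, flat_env):
        pres = uniform_points(40, 11)
        bg = uniform_points(200, 12)
        evals = cross_validate({"null": "null", "envelope": "envelope"},
                               pres, bg, flat_env, seed=1)
        members, cauc, table = best_ensemble(
            ["envelope"], evals, {"envelope": "envelope"}, pres, bg, flat_env, seed=1
        )
        assert members == ("envelope",)
        assert set(table) == {("envelope",)}

    def test_combinatorial_guard(self, flat_env):
        ids = [f"m{i}" for i in range(13)]
        evals = {i: sdm.EvaluationSet(i, np.full(10, 0.8)) for i in ids}
        with pytest.raises(ValueError, match="guard"):
            best_ensemble(ids, evals, {}, uniform_points(20, 0),
                          uniform_points(50, 1), flat_env)


class TestThresholdMaxSS:
    def test_perfect_separation_lowest_midpoint(self):
        t = threshold_max_ss([0.8, 0.9], [0.1, 0.2])
        assert t == pytest.approx((0.2 + 0.8) / 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.random(4)
        neg = rng.random(4)
        t = threshold_max_ss(pos, neg)
        uniq = np.unique(np.r_[pos, neg])
        cands = (uniq[:-1] + uniq[1:]) / 2

        def ss(thr):
            return np.mean(pos >= thr) + np.mean(neg < thr)

        best = max(ss(c) for c in cands)
        assert ss(t) == pytest.approx(best)
        # lowest among the maximizers
        assert all(t <= c + 1e-12 for c in cands if ss(c) == pytest.approx(best))

    def test_degenerate_scores_signalled(self):
        with pytest.raises(ValueError):
            threshold_max_ss([0.5, 0.5], [0.5])


class TestProjectAndScenarios:
    def test_projection_thresholds_to_nodata(self, small_world):
        m = GeographicNullModel([-70.0], [0.0])
        full = sdm.project(m, small_world.env_current)
        thr = 0.01  # keeps only cells within ~100 km of the presence
        r = sdm.project(m, small_world.env_current, threshold=thr)
        assert 0 < r.valid_mask.sum() < full.valid_mask.sum()
        assert np.all(r.valid_values >= thr)

    def test_missing_variable_rejected(self, small_world, flat_env):
        pres = synth.generate_presences(small_world, 30, 30, seed=1)
        env = small_world.env_current
        vals = env.extract(pres["lon"].to_numpy(), pres["lat"].to_numpy()).dropna()
        model = EnvelopeModel(vals)
        from divscape.stack import EnvStack

        partial = EnvStack({env.names[0]: env[env.names[0]]})
        with pytest.raises(ValueError, match="lacks"):
            sdm.project(model, partial)

    def test_identical_maps_average_to_themselves(self):
        g = GridRaster((0.0, 1.0, 0.0, 1.0), 30.0, np.array([[0.6, np.nan], [0.7, 0.9]]))
        out = summarize_scenarios([g, g.like(g.values.copy())], threshold=0.5)
        assert np.allclose(out.values[g.valid_mask], g.values[g.valid_mask])

    def test_partial_suitability_halves_mean(self):
        a = GridRaster((0.0, 0.5, 0.0, 0.5), 30.0, np.array([[0.6]]))
        b = a.like(np.array([[np.nan]]))
        out = summarize_scenarios([a, b], threshold=0.5)
        assert out.values[0, 0] == pytest.approx(0.3)

    def test_restrict_empties_map_when_threshold_high(self):
        a = GridRaster((0.0, 0.5, 0.0, 0.5), 30.0, np.array([[0.6]]))
        out = summarize_scenarios([a], threshold=0.9, restrict=True)
        assert np.isnan(out.values).all()


class TestEnsembleSDMFacade:
    def test_fit_summary_and_projection(self, small_world):
        pres = synth.generate_presences(small_world, 40, 120, seed=2)
        pres = pres[pres["variety"] == "cultivated"].reset_index(drop=True)
        env = small_world.env_current
        bg = sample_background(
            env.grid.like(np.where(env.valid_mask(), 1.0, np.nan)), 350, 2
        )
        res = EnsembleSDM(pres, bg, env).fit(seed=2)
        txt = res.summary()
        assert "mean cAUC" in txt and "null" in txt
        table = res.evaluation_table
        assert set(table["model"]) >= {"envelope", "regression", "null"}
        assert (table.groupby("model").size() == 10).all()
        if res.ensemble is not None:
            r = res.project()
            assert np.all(r.valid_values >= res.threshold)
            alt = res.project(small_world.env_alt["alt1"])
            assert alt.same_geometry(r)

    def test_null_calibration_property_over_seeds(self, flat_env):
        """|mean cAUC(null) - 0.5| <= 0.05 on each of 10 unbiased seeds."""
        devs = []
        for seed in range(10):
            evals = cross_validate(
                {"null": "null"},
                uniform_points(80, 100 + seed), uniform_points(800, 200 + seed),
                flat_env, seed=seed,
            )
            devs.append(abs(evals["null"].mean_cauc - 0.5))
        assert np.mean(devs) <= 0.05
        assert max(devs) <= 0.1
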