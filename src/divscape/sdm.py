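"""Ensemble habitat-suitability modelling with geographic-null calibration.

The modelling protocol, not any single algorithm, is the point here:

1. fit several component suitability models plus an inverse-distance
   *geographic null* on presence/background points;
2. evaluate every model by 5-fold x 2-repeat cross-validation, removing
   spatial sorting bias (SSB) from each held-out partition by pairwise
   distance matching before computing AUC — the *calibrated AUC* (cAUC);
3. retain only models whose ten cAUCs beat the null's (one-sided
   Mann-Whitney, p < 0.05);
4. search all ensembles (subsets) of retained models, each predicting
   the cAUC-weighted mean of its members, and keep the ensemble with the
   highest mean cAUC;
5. threshold at maximum training sensitivity + specificity and project
   to alternative climate stacks, averaging threshold-limited maps
   across scenarios.

The component set shipped here is a percentile envelope (BIOCLIM-style),
a quadratic logistic regression, and the geographic null; the ensemble
machinery is model-agnostic via the ``SuitabilityModel`` interface, so
further members can be plugged in.

The user-facing surface follows the model/results idiom:
``EnsembleSDM(presences, background, env).fit(seed=...)`` returns an
:class:`EnsembleSDMResults` carrying the evaluation table, retained set,
weights, threshold and projection methods.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geo import min_distance_to_set_km
from .raster import GridRaster
from .stack import EnvStack

__all__ = [
    "SuitabilityModel",
    "EnvelopeModel",
    "RegressionModel",
    "GeographicNullModel",
    "EnsembleModel",
    "EvaluationSet",
    "EnsembleSDM",
    "EnsembleSDMResults",
    "sample_background",
    "remove_ssb",
    "auc",
    "cross_validate",
    "retain_models",
    "best_ensemble",
    "threshold_max_ss",
    "project",
    "summarize_scenarios",
    "MODEL_KINDS",
]


# -- component models -------------------------------------------------------


class SuitabilityModel:
    """Interface: a fitted model scoring suitability in [0, 1].

    Subclasses implement :meth:`score` over point locations given an
    environment stack (purely environmental models ignore the locations'
    geography; the geographic null ignores the environment).
    """

    kind: str = "abstract"

    def score(self, lon: np.ndarray, lat: np.ndarray, env: EnvStack) -> np.ndarray:
        raise NotImplementedError

    def score_grid(self, env: EnvStack) -> GridRaster:
        """Suitability on every jointly valid cell of a stack."""
        mask = env.valid_mask()
        clon, clat = env.grid.cell_centers()
        vals = np.full(env.shape, np.nan)
        vals[mask] = self.score(clon[mask], clat[mask], env)
        return env.grid.like(vals)


class EnvelopeModel(SuitabilityModel):
    """Percentile-envelope (BIOCLIM-style) model.

    Per variable the score is ``2 * min(F(x), 1 - F(x))`` with F the
    mid-rank empirical CDF of the presence values (1 at the presence
    median, 0 outside the presence range); the overall score is the
    minimum over variables. Constant variables are dropped.
    """

    kind = "envelope"

    def __init__(self, presence_env: pd.DataFrame):
        if len(presence_env) < 5:
            raise ValueError("need at least 5 presences to fit an envelope")
        self.sorted_vals: dict[str, np.ndarray] = {}
        for col in presence_env.columns:
            v = np.sort(presence_env[col].to_numpy(dtype=float))
            if v[0] == v[-1]:
                continue  # constant variable carries no envelope information
            self.sorted_vals[col] = v
        if not self.sorted_vals:
            raise ValueError("all variables constant: envelope undefined")

    def score_env(self, X: pd.DataFrame) -> np.ndarray:
        scores = np.ones(len(X))
        for col, v in self.sorted_vals.items():
            x = X[col].to_numpy(dtype=float)
            n = v.size
            left = np.searchsorted(v, x, side="left")
            right = np.searchsorted(v, x, side="right")
            F = (left + right) / (2.0 * n)  # mid-rank CDF
            s = 2.0 * np.minimum(F, 1.0 - F)
            scores = np.minimum(scores, np.clip(s, 0.0, 1.0))
        return scores

    def score(self, lon, lat, env: EnvStack) -> np.ndarray:
        return self.score_env(env.extract(lon, lat))


class RegressionModel(SuitabilityModel):
    """Logistic regression of presence vs background on linear + quadratic terms.

    Fitted by Newton/IRLS (statsmodels) to gradient norm < 1e-8 within 100
    iterations; on complete separation or non-convergence an L2-penalised
    fit (ridge 1e-4) is used instead and the event logged as a warning.
    """

    kind = "regression"

    def __init__(self, presence_env: pd.DataFrame, background_env: pd.DataFrame):
        if len(presence_env) < 10 or len(background_env) < 10:
            raise ValueError("need at least 10 presences and 10 background points")
        X = pd.concat([presence_env, background_env], ignore_index=True)
        y = np.r_[np.ones(len(presence_env)), np.zeros(len(background_env))]
        keep = [c for c in X.columns if X[c].std() > 0]
        self.columns = keep
        self.means = X[keep].mean()
        self.scales = X[keep].std().replace(0.0, 1.0)
        D = self._design(X)
        self.coef = self._fit(D, y)

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        Z = ((X[self.columns] - self.means) / self.scales).to_numpy(dtype=float)
        return np.column_stack([np.ones(len(Z)), Z, Z**2])

    @staticmethod
    def _fit(D: np.ndarray, y: np.ndarray) -> np.ndarray:
        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, D).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
                if res.mle_retvals.get("converged", False):
                    return np.asarray(res.params)
            except (PerfectSeparationError, np.linalg.LinAlgError, Exception):
                pass
        warnings.warn("logistic fit did not converge; using ridge fallback (1e-4)")
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(penalty="l2", C=1.0 / 1e-4, fit_intercept=False, max_iter=1000)
        lr.fit(D, y)
        return lr.coef_.ravel()

    def score_env(self, X: pd.DataFrame) -> np.ndarray:
        eta = self._design(X) @ self.coef
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))

    def score(self, lon, lat, env: EnvStack) -> np.ndarray:
        return self.score_env(env.extract(lon, lat))


class GeographicNullModel(SuitabilityModel):
    """Inverse-distance null: score = 1 / (1 + d), d in km to nearest presence.

    The benchmark any environmental model must beat; monotone decreasing
    in distance, exactly 1 at a training presence.
    """

    kind = "geographic_null"

    def __init__(self, presence_lon: np.ndarray, presence_lat: np.ndarray):
        lon = np.atleast_1d(np.asarray(presence_lon, dtype=float))
        if lon.size == 0:
            raise ValueError("need at least one presence")
        self.presence_lon = lon
        self.presence_lat = np.atleast_1d(np.asarray(presence_lat, dtype=float))

    def score(self, lon, lat, env: EnvStack | None = None) -> np.ndarray:
        d = min_distance_to_set_km(np.atleast_1d(lon), np.atleast_1d(lat),
                                   self.presence_lon, self.presence_lat)
        return 1.0 / (1.0 + d)


@dataclass
class EnsembleModel(SuitabilityModel):
    """cAUC-weighted average of fitted member models."""

    members: list[str]
    weights: np.ndarray
    models: list[SuitabilityModel]
    threshold: float | None = None
    kind: str = field(default="ensemble")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        self.weights = self.weights / total

    def score(self, lon, lat, env: EnvStack) -> np.ndarray:
        parts = [m.score(lon, lat, env) for m in self.models]
        return np.tensordot(self.weights, np.vstack(parts), axes=1)


MODEL_KINDS = ("envelope", "regression", "null")


def _fit_component(kind: str, pres: pd.DataFrame, bg: pd.DataFrame, env: EnvStack) -> SuitabilityModel:
    if kind == "envelope":
        return EnvelopeModel(env.extract(pres["lon"].to_numpy(), pres["lat"].to_numpy()).dropna())
    if kind == "regression":
        pe = env.extract(pres["lon"].to_numpy(), pres["lat"].to_numpy()).dropna()
        be = env.extract(bg["lon"].to_numpy(), bg["lat"].to_numpy()).dropna()
        return RegressionModel(pe, be)
    if kind == "null":
        return GeographicNullModel(pres["lon"].to_numpy(), pres["lat"].to_numpy())
    raise ValueError(f"unknown model kind {kind!r}")


# -- evaluation machinery ---------------------------------------------------


def sample_background(region: GridRaster, n: int, seed: int | None = None) -> pd.DataFrame:
    """Sample n distinct valid cells uniformly; returns their center coordinates."""
    mask = region.valid_mask
    clon, clat = region.cell_centers()
    lons, lats = clon[mask], clat[mask]
    if n > lons.size:
        raise ValueError(f"requested {n} background cells, only {lons.size} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(lons.size, size=n, replace=False)
    return pd.DataFrame({"lon": lons[idx], "lat": lats[idx]})


def remove_ssb(
    test_presences: pd.DataFrame,
    test_absences: pd.DataFrame,
    train_presences: pd.DataFrame,
    tolerance: float = 0.33,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise distance sampling to remove spatial sorting bias.

    Each test presence (distance ``d_p`` to the nearest training presence)
    is greedily matched, in increasing order of ``d_p``, to an unused test
    absence whose distance ``d_a`` satisfies ``|d_a - d_p| / d_p <=
    tolerance``; unmatched presences are dropped. Returns positional index
    arrays (presences, matched absences). A warning is raised when fewer
    than 20% of presences could be matched (the resulting cAUC is then
    unreliable).
    """
    if len(test_presences) == 0 or len(test_absences) == 0 or len(train_presences) == 0:
        raise ValueError("all three point sets must be non-empty")
    d_p = min_distance_to_set_km(
        test_presences["lon"].to_numpy(), test_presences["lat"].to_numpy(),
        train_presences["lon"].to_numpy(), train_presences["lat"].to_numpy(),
    )
    d_a = min_distance_to_set_km(
        test_absences["lon"].to_numpy(), test_absences["lat"].to_numpy(),
        train_presences["lon"].to_numpy(), train_presences["lat"].to_numpy(),
    )
    order = np.argsort(d_p, kind="stable")
    used = np.zeros(len(d_a), dtype=bool)
    pres_idx, abs_idx = [], []
    for i in order:
        dp = max(d_p[i], 1e-9)
        rel = np.abs(d_a - dp) / dp
        rel[used] = np.inf
        j = int(np.argmin(rel))
        if rel[j] <= tolerance:
            used[j] = True
            pres_idx.append(int(i))
            abs_idx.append(j)
    if len(pres_idx) < 0.2 * len(d_p):
        warnings.warn(
            f"only {len(pres_idx)}/{len(d_p)} test presences matched; cAUC unreliable"
        )
    return np.array(pres_idx, dtype=int), np.array(abs_idx, dtype=int)


def ssb_ratio(test_presences, test_absences, train_presences) -> float:
    """mean(d_presence) / mean(d_absence), distances to nearest training presence."""
    d_p = min_distance_to_set_km(
        test_presences["lon"].to_numpy(), test_presences["lat"].to_numpy(),
        train_presences["lon"].to_numpy(), train_presences["lat"].to_numpy(),
    )
    d_a = min_distance_to_set_km(
        test_absences["lon"].to_numpy(), test_absences["lat"].to_numpy(),
        train_presences["lon"].to_numpy(), train_presences["lat"].to_numpy(),
    )
    return float(d_p.mean() / d_a.mean())


def auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of (pos, neg) pairs ranked correctly, ties = 1/2."""
    pos = np.atleast_1d(np.asarray(scores_pos, dtype=float))
    neg = np.atleast_1d(np.asarray(scores_neg, dtype=float))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (pos.size * neg.size))


@dataclass
class EvaluationSet:
    """The k x repeats calibrated-AUC values for one model."""

    model: str
    cauc_values: np.ndarray  # NaN marks rounds with an empty SSB-corrected test set

    @property
    def mean_cauc(self) -> float:
        return float(np.nanmean(self.cauc_values))


def _partitions(n: int, k: int, rng) -> np.ndarray:
    """Fold label per index: a random permutation cut into k near-equal groups."""
    labels = np.arange(n) % k
    return labels[rng.permutation(n)]


def cross_validate(
    model_kinds,
    presences: pd.DataFrame,
    background: pd.DataFrame,
    env: EnvStack,
    k: int = 5,
    repeats: int = 2,
    seed: int = 0,
    ssb_tolerance: float = 0.33,
    fit_fn=None,
) -> dict[str, EvaluationSet]:
    """k-fold x repeats cAUC evaluation with SSB removal, shared partitions.

    ``model_kinds`` maps a model id to either a kind name from
    ``MODEL_KINDS`` or a callable ``(train_pres, train_bg, env) -> model``.
    All models see identical partitions; a round whose SSB-corrected test
    set is empty is recorded as NaN for every model and later excluded
    pairwise.
    """
    if len(presences) < k or len(background) < k:
        raise ValueError(f"need at least {k} presences and background points")
    n_rounds = k * repeats
    caucs = {mid: np.full(n_rounds, np.nan) for mid in model_kinds}
    round_i = 0
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        pres_fold = _partitions(len(presences), k, rng)
        bg_fold = _partitions(len(background), k, rng)
        for fold in range(k):
            train_p = presences.iloc[pres_fold != fold].reset_index(drop=True)
            test_p = presences.iloc[pres_fold == fold].reset_index(drop=True)
            train_b = background.iloc[bg_fold != fold].reset_index(drop=True)
            test_b = background.iloc[bg_fold == fold].reset_index(drop=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pi, ai = remove_ssb(test_p, test_b, train_p, ssb_tolerance)
            if pi.size == 0:
                round_i += 1
                continue
            mp = test_p.iloc[pi]
            mb = test_b.iloc[ai]
            for mid, spec in model_kinds.items():
                if callable(spec):
                    model = spec(train_p, train_b, env)
                else:
                    model = (fit_fn or _fit_component)(spec, train_p, train_b, env)
                sp = model.score(mp["lon"].to_numpy(), mp["lat"].to_numpy(), env)
                sn = model.score(mb["lon"].to_numpy(), mb["lat"].to_numpy(), env)
                caucs[mid][round_i] = auc(sp, sn)
            round_i += 1
    return {mid: EvaluationSet(mid, vals) for mid, vals in caucs.items()}


def retain_models(
    evals: dict[str, EvaluationSet],
    null_eval: EvaluationSet,
    alpha: float = 0.05,
) -> list[str]:
    """Keep models whose cAUCs beat the null's (one-sided Mann-Whitney, p < alpha)."""
    retained = []
    for mid, ev in evals.items():
        if mid == null_eval.model:
            continue
        both = ~(np.isnan(ev.cauc_values) | np.isnan(null_eval.cauc_values))
        x = ev.cauc_values[both]
        y = null_eval.cauc_values[both]
        if x.size == 0:
            continue
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            continue  # identical constants: no evidence over the null
        _, p = sps.mannwhitneyu(x, y, alternative="greater")
        if p < alpha:
            retained.append(mid)
    return retained


def _ensemble_factory(member_ids, weights, base_specs, fit_fn=None):
    def factory(train_p, train_b, env):
        models = []
        for mid in member_ids:
            spec = base_specs[mid]
            if callable(spec):
                models.append(spec(train_p, train_b, env))
            else:
                models.append((fit_fn or _fit_component)(spec, train_p, train_b, env))
        return EnsembleModel(list(member_ids), np.asarray(weights, dtype=float), models)

    return factory


def best_ensemble(
    retained: list[str],
    evals: dict[str, EvaluationSet],
    model_specs: dict,
    presences: pd.DataFrame,
    background: pd.DataFrame,
    env: EnvStack,
    k: int = 5,
    repeats: int = 2,
    seed: int = 0,
    max_members: int = 12,
    ssb_tolerance: float = 0.33,
) -> tuple[tuple[str, ...], float, dict[tuple[str, ...], float]]:
    """Search all member subsets of the retained models for the highest mean cAUC.

    Every subset predicts the weighted mean of its members' scores, with
    each member weighted by its global mean cAUC (renormalized within the
    subset); subsets are evaluated by the same k x repeats cAUC protocol
    with the same seed (hence identical partitions). Ties prefer the
    smaller subset, then lexicographic member order. Returns the winning
    member tuple, its mean cAUC, and the full subset -> mean cAUC table.
    """
    if not retained:
        raise ValueError("no retained models to ensemble")
    if len(retained) > max_members:
        raise ValueError(
            f"{len(retained)} retained models exceed the combinatorial guard "
            f"({max_members}); raise max_members explicitly to proceed"
        )
    global_weights = {mid: evals[mid].mean_cauc for mid in retained}
    subsets = []
    for size in range(1, len(retained) + 1):
        subsets.extend(itertools.combinations(sorted(retained), size))
    ensemble_specs = {
        "|".join(sub): _ensemble_factory(sub, [global_weights[m] for m in sub], model_specs)
        for sub in subsets
    }
    results = cross_validate(
        ensemble_specs, presences, background, env, k=k, repeats=repeats,
        seed=seed, ssb_tolerance=ssb_tolerance,
    )
    table = {tuple(key.split("|")): ev.mean_cauc for key, ev in results.items()}
    best = min(table, key=lambda sub: (-round(table[sub], 12), len(sub), sub))
    return best, table[best], table


def threshold_max_ss(scores_pres: np.ndarray, scores_bg: np.ndarray) -> float:
    """Maximum training sensitivity + specificity threshold.

    Candidates are the midpoints between consecutive sorted unique scores;
    a point is predicted suitable when its score >= threshold. Ties take
    the lowest threshold. Degenerate when all scores are equal.
    """
    pos = np.asarray(scores_pres, dtype=float)
    neg = np.asarray(scores_bg, dtype=float)
    uniq = np.unique(np.r_[pos, neg])
    if uniq.size < 2:
        raise ValueError("all scores equal: threshold degenerate")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_ss = None, -np.inf
    for t in candidates:
        sens = np.mean(pos >= t)
        spec = np.mean(neg < t)
        ss = sens + spec
        if ss > best_ss + 1e-12:
            best_ss, best_t = ss, t
    return float(best_t)


def project(model: SuitabilityModel, env: EnvStack, threshold: float | None = None) -> GridRaster:
    """Score a model on every valid cell; cells below the threshold -> nodata."""
    missing = [c for c in getattr(model, "columns", []) if c not in env.names]
    for m in getattr(model, "models", []):
        missing += [c for c in getattr(m, "columns", []) if c not in env.names]
        missing += [c for c in getattr(m, "sorted_vals", {}) if c not in env.names]
    missing += [c for c in getattr(model, "sorted_vals", {}) if c not in env.names]
    if missing:
        raise ValueError(f"stack lacks calibration variables: {sorted(set(missing))}")
    r = model.score_grid(env)
    if threshold is not None:
        vals = r.values.copy()
        vals[vals < threshold] = np.nan
        r = r.like(vals)
    return r


def summarize_scenarios(
    maps: list[GridRaster], threshold: float, restrict: bool = False
) -> GridRaster:
    """Average threshold-limited suitability maps across climate scenarios.

    Nodata cells (below-threshold in a scenario) contribute 0 to the mean,
    so a cell suitable in only some scenarios is down-weighted. With
    ``restrict=True`` cells whose mean falls below the threshold are set
    to nodata (the rule applied to future-scenario summaries).
    """
    if not maps:
        raise ValueError("need at least one map")
    first = maps[0]
    for m in maps[1:]:
        if not first.same_geometry(m):
            raise ValueError("raster geometries do not match")
    stack = np.stack([np.where(m.valid_mask, m.values, 0.0) for m in maps])
    mean = stack.mean(axis=0)
    if restrict:
        mean = np.where(mean < threshold, np.nan, mean)
    return first.like(mean)


# -- model/results facade ---------------------------------------------------


class EnsembleSDM:
    """Ensemble suitability model specification bound to data.

    Parameters
    ----------
    presences, background : DataFrame with ``lon``/``lat`` columns.
    env : EnvStack
        Calibration-climate predictor stack.
    models : sequence of str
        Component kinds to consider (from ``MODEL_KINDS``, excluding the
        null, which is always evaluated as the benchmark).
    """

    def __init__(
        self,
        presences: pd.DataFrame,
        background: pd.DataFrame,
        env: EnvStack,
        models=("envelope", "regression"),
        k: int = 5,
        repeats: int = 2,
        alpha: float = 0.05,
        ssb_tolerance: float = 0.33,
        max_members: int = 12,
    ):
        self.presences = presences.reset_index(drop=True)
        self.background = background.reset_index(drop=True)
        self.env = env
        self.model_kinds = list(models)
        if "null" in self.model_kinds:
            self.model_kinds.remove("null")
        self.k = k
        self.repeats = repeats
        self.alpha = alpha
        self.ssb_tolerance = ssb_tolerance
        self.max_members = max_members

    def fit(self, seed: int = 0) -> "EnsembleSDMResults":
        specs = {mid: mid if mid != "null" else "null" for mid in self.model_kinds}
        specs["null"] = "null"
        evals = cross_validate(
            specs, self.presences, self.background, self.env,
            k=self.k, repeats=self.repeats, seed=seed,
            ssb_tolerance=self.ssb_tolerance,
        )
        null_eval = evals["null"]
        retained = retain_models(
            {m: e for m, e in evals.items() if m != "null"}, null_eval, self.alpha
        )
        members: tuple[str, ...] = ()
        best_cauc = np.nan
        ensemble = None
        threshold = np.nan
        if retained:
            members, best_cauc, _ = best_ensemble(
                retained, evals, specs, self.presences, self.background, self.env,
                k=self.k, repeats=self.repeats, seed=seed,
                max_members=self.max_members, ssb_tolerance=self.ssb_tolerance,
            )
            weights = np.array([evals[m].mean_cauc for m in members])
            fitted = [
                _fit_component(m, self.presences, self.background, self.env)
                for m in members
            ]
            ensemble = EnsembleModel(list(members), weights, fitted)
            sp = ensemble.score(
                self.presences["lon"].to_numpy(), self.presences["lat"].to_numpy(), self.env
            )
            sb = ensemble.score(
                self.background["lon"].to_numpy(), self.background["lat"].to_numpy(), self.env
            )
            threshold = threshold_max_ss(sp, sb)
            ensemble.threshold = threshold
        return EnsembleSDMResults(self, evals, retained, ensemble, threshold, seed)


class EnsembleSDMResults:
    """Fitted ensemble, its evaluation table, and projection methods."""

    def __init__(self, model: EnsembleSDM, evals, retained, ensemble, threshold, seed):
        self.model = model
        self.evals = evals
        self.retained = retained
        self.ensemble = ensemble
        self.threshold = threshold
        self.seed = seed

    @property
    def evaluation_table(self) -> pd.DataFrame:
        """Long-format table: model, repeat, fold, cauc."""
        k = self.model.k
        recs = []
        for mid, ev in self.evals.items():
            for i, v in enumerate(ev.cauc_values):
                recs.append(
                    {"model": mid, "repeat": i // k, "fold": i % k, "cauc": v}
                )
        return pd.DataFrame(recs)

    def project(self, env: EnvStack | None = None, limit: bool = True) -> GridRaster:
        """Suitability map on a climate stack (default: calibration climate)."""
        if self.ensemble is None:
            raise ValueError("no model was retained over the null; nothing to project")
        return project(
            self.ensemble, env or self.model.env,
            self.threshold if limit else None,
        )

    def summary(self) -> str:
        lines = ["Ensemble suitability model", "=" * 40]
        lines.append(f"{'model':<24}{'mean cAUC':>10}")
        for mid, ev in sorted(self.evals.items()):
            tag = ""
            if mid in self.retained:
                tag = " (retained)"
            elif mid == "null":
                tag = " (benchmark)"
            lines.append(f"{mid:<24}{ev.mean_cauc:>10.3f}{tag}")
        if self.ensemble is not None:
            lines.append("")
            lines.append(f"best ensemble: {' & '.join(self.ensemble.members)}")
            w = ", ".join(
                f"{m}={w:.3f}" for m, w in zip(self.ensemble.members, self.ensemble.weights)
            )
            lines.append(f"weights: {w}")
            lines.append(f"max sens+spec threshold: {self.threshold:.4f}")
        else:
            lines.append("no model significantly outperformed the geographic null")
        return "\n".join(lines)

    def plot_map(self, raster: GridRaster | None = None, ax=None, **imshow_kw):
        """Render a suitability map (default: calibration projection)."""
        import matplotlib.pyplot as plt

        r = raster if raster is not None else self.project()
        if ax is None:
            _, ax = plt.subplots()
        lon_min, lon_max, lat_min, lat_max = r.extent
        im = ax.imshow(
            r.values, extent=(lon_min, lon_max, lat_min, lat_max),
            origin="upper", **imshow_kw,
        )
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        return im
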