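"""Design coding, the Gibbs sampler against conjugate oracles, decision rule."""

import json

import numpy as np
import pandas as pd
import pytest

from c4drought import synthetic as syn
from c4drought.bayes_anova import (
    DesignMatrix,
    MCMCSettings,
    PosteriorDraws,
    PriorSpec,
    anova_report,
    build_design,
    cell_weights,
    contrast_weights,
    directional_probability,
    ridge_posterior_mean,
    sample_posterior,
)


def _factorial(n_reps=5, residual_sd=1.0, seed=0, effect=0.0, weeks=(2, 4)):
    means = {
        ("x", tr, wk): (effect if tr == "drought" else 0.0)
        for tr in ("control", "drought")
        for wk in weeks
    }
    truth = syn.FactorialTruth(
        species=("x",), treatments=("control", "drought"), weeks=weeks,
        cell_means=means, n_reps=n_reps, residual_sd=residual_sd, seed=seed,
    )
    return syn.gen_factorial(truth)


class TestBuildDesign:
    def test_one_way_two_levels(self):
        df = _factorial(weeks=(1,))
        d = build_design(df, ["treatment"])
        assert d.k == 2
        assert d.labels == ["intercept", "treatment=drought"]

    def test_two_way_with_interaction_column_count(self):
        df = pd.DataFrame(
            {"treatment": np.repeat(["c", "d"], 8),
             "week": list(np.tile([1, 3, 5, 7], 4)),
             "y": np.zeros(16)}
        )
        d = build_design(df, ["treatment", "week"], interaction=True)
        assert d.k == 1 + 1 + 3 + 3

    def test_unbalanced_rows_kept(self):
        df = pd.DataFrame({"treatment": ["c"] * 13 + ["d"] * 10, "y": np.zeros(23)})
        assert build_design(df, ["treatment"]).X.shape[0] == 23

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"treatment": ["c"] * 5, "y": np.zeros(5)})
        with pytest.raises(ValueError):
            build_design(df, ["treatment"])

    def test_empty_cell_warns(self):
        df = pd.DataFrame(
            {"treatment": ["c", "c", "d"], "week": [1, 2, 1], "y": [0.0, 0.0, 0.0]}
        )
        with pytest.warns(UserWarning):
            build_design(df, ["treatment", "week"], interaction=True)

    def test_within_week_contrast_has_two_nonzero_entries(self):
        df = pd.DataFrame(
            {"treatment": np.repeat(["control", "drought"], 8),
             "week": list(np.tile([1, 3, 5, 7], 4))}
        )
        d = build_design(df, ["treatment", "week"], interaction=True)
        w = contrast_weights(
            d, {"treatment": "drought", "week": 3}, {"treatment": "control", "week": 3}
        )
        # intercept and week dummies cancel; treatment dummy + interaction remain
        assert int(np.count_nonzero(w)) == 2
        assert w[d.labels.index("treatment=drought")] == 1.0
        assert w[d.labels.index("treatment=drought:week=3")] == 1.0

    def test_cell_weights_reproduce_design_rows(self):
        df = pd.DataFrame(
            {"treatment": ["control", "drought", "drought"], "week": [1, 1, 3]}
        )
        with pytest.warns(UserWarning, match="empty"):
            d = build_design(df, ["treatment", "week"], interaction=True)
        for i in range(len(df)):
            w = cell_weights(d, {"treatment": df["treatment"][i], "week": df["week"][i]})
            assert np.allclose(w, d.X[i])


class TestSampler:
    def test_fixed_variance_posterior_matches_ridge(self):
        df = _factorial(n_reps=6, seed=3)
        d = build_design(df, ["treatment", "week"], interaction=True)
        y = df["value"].to_numpy()
        prior = PriorSpec(fixed_sigma2=1.3, fixed_sigma_b2=2.0)
        draws = sample_posterior(y, d, prior, MCMCSettings(2, 100, 2000, seed=5))
        pooled = np.ones(d.k, bool)
        pooled[0] = False
        fp = np.zeros(d.k)
        fp[0] = 1.0 / (10 * np.std(y, ddof=1)) ** 2
        pm = np.zeros(d.k)
        pm[0] = y.mean()
        oracle = ridge_posterior_mean(y, d.X, 1.3, 2.0, pooled, pm, fp)
        mc_mean = draws.draws.mean(axis=0)
        mc_se = draws.draws.std(axis=0) / np.sqrt(draws.draws.shape[0])
        assert np.all(np.abs(mc_mean - oracle) <= 3 * mc_se)

    def test_zero_response_gives_zero_pooled_means(self):
        df = _factorial(n_reps=6, residual_sd=0.0, seed=0)
        df["value"] = 0.0
        d = build_design(df, ["treatment", "week"])
        # tiny fixed residual variance keeps the likelihood proper at y == 0
        prior = PriorSpec(fixed_sigma2=1.0)
        draws = sample_posterior(df["value"].to_numpy(), d, prior,
                                 MCMCSettings(2, 200, 1000, seed=1))
        mc_mean = draws.draws.mean(axis=0)[1:]
        mc_se = draws.draws.std(axis=0)[1:] / np.sqrt(draws.draws.shape[0])
        assert np.all(np.abs(mc_mean) <= 4 * np.maximum(mc_se, 1e-12))

    def test_shrinkage_toward_zero_with_orthonormal_columns(self):
        rng = np.random.default_rng(7)
        Q, _ = np.linalg.qr(rng.standard_normal((40, 3)))
        X = Q[:, :3]
        y = X @ np.array([2.0, -1.0, 0.5]) + rng.normal(0, 0.5, 40)
        d = DesignMatrix(X=X, labels=["c1", "c2", "c3"], coding="reference",
                         factor_map={}, levels={}, interaction=False)
        ols = X.T @ y  # orthonormal columns: OLS is the projection
        prior = PriorSpec(fixed_sigma2=0.25, fixed_sigma_b2=1.0, pool_intercept=True)
        draws = sample_posterior(y, d, prior, MCMCSettings(2, 100, 3000, seed=2))
        post = draws.draws.mean(axis=0)
        assert np.all(np.abs(post) < np.abs(ols))
        # closed form: shrink factor (1/s2)/(1/s2 + 1/sb2)
        assert np.allclose(post, ols * (4.0 / 5.0), atol=0.05)

    def test_posterior_mean_approaches_ols_at_large_n(self):
        rng = np.random.default_rng(8)
        n = 10_000
        df = pd.DataFrame({"treatment": rng.choice(["c", "d"], n)})
        df["value"] = (df["treatment"] == "d") * 1.0 + rng.normal(0, 1, n)
        d = build_design(df, ["treatment"])
        draws = sample_posterior(df["value"].to_numpy(), d,
                                 mcmc=MCMCSettings(2, 200, 500, seed=3))
        ols, *_ = np.linalg.lstsq(d.X, df["value"].to_numpy(), rcond=None)
        eff = d.labels.index("treatment=d")
        assert draws.draws.mean(axis=0)[eff] == pytest.approx(ols[eff], rel=0.01)

    def test_strong_effect_detected(self):
        hits = 0
        for seed in range(20):
            df = _factorial(n_reps=10, effect=5.0, seed=seed)
            d = build_design(df, ["treatment", "week"], interaction=True)
            draws = sample_posterior(df["value"].to_numpy(), d,
                                     mcmc=MCMCSettings(2, 300, 500, seed=seed))
            j = d.labels.index("treatment=drought")
            w = np.zeros(d.k)
            w[j] = 1.0
            hits += directional_probability(draws, w, ">0").pr > 0.95
        assert hits >= 19

    def test_nan_response_rejected(self):
        df = _factorial()
        d = build_design(df, ["treatment"])
        y = df["value"].to_numpy()
        y[0] = np.nan
        with pytest.raises(ValueError):
            sample_posterior(y, d)


def _draws_from(matrix):
    matrix = np.asarray(matrix, dtype=float)
    return PosteriorDraws(
        draws=matrix,
        sigma2_draws=np.ones(len(matrix)),
        sigma_b2_draws=np.ones(len(matrix)),
        labels=[f"c{i}" for i in range(matrix.shape[1])],
        rhat={}, ess={}, converged=True,
        settings=MCMCSettings(),
    )


class TestDecisionRule:
    def test_all_positive_draws_significant(self):
        d = _draws_from(np.ones((4000, 1)))
        s = directional_probability(d, [1.0], ">0")
        assert s.pr == 1.0 and s.significance == "significant"

    def test_moderate_band(self):
        col = np.concatenate([np.ones(937), -np.ones(63)])
        s = directional_probability(_draws_from(col[:, None]), [1.0], ">0")
        assert s.pr == pytest.approx(0.937)
        assert s.significance == "moderate"

    def test_symmetric_null_is_none(self):
        rng = np.random.default_rng(0)
        s = directional_probability(_draws_from(rng.standard_normal((20000, 1))), [1.0], ">0")
        assert abs(s.pr - 0.5) < 0.02
        assert s.significance == "none"

    def test_directions_are_complementary(self):
        rng = np.random.default_rng(1)
        d = _draws_from(rng.standard_normal((5000, 2)))
        pos = directional_probability(d, [1.0, 0.5], ">0").pr
        neg = directional_probability(d, [1.0, 0.5], "<0").pr
        assert pos + neg == pytest.approx(1.0, abs=1e-12)

    def test_zero_contrast_rejected(self):
        with pytest.raises(ValueError):
            directional_probability(_draws_from(np.ones((10, 2))), [0.0, 0.0], ">0")


class TestAnovaReport:
    def test_report_is_deterministic_given_seed(self):
        df = _factorial(seed=4)
        kw = dict(response="value", factors=["treatment", "week"], interaction=True,
                  mcmc=MCMCSettings(2, 200, 300, seed=9))
        a = anova_report(df, **kw)
        b = anova_report(df, **kw)
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_cell_contrast_reported(self):
        df = _factorial(effect=4.0, n_reps=8, seed=5)
        rep = anova_report(
            df, "value", ["treatment", "week"], interaction=True,
            mcmc=MCMCSettings(2, 300, 500, seed=2),
            cell_contrasts=[{
                "name": "drought < control | week 4",
                "a": {"treatment": "drought", "week": 4},
                "b": {"treatment": "control", "week": 4},
                "direction": "<0",
            }],
        )
        labels = [c["label"] for c in rep["contrasts"]]
        assert "drought < control | week 4" in labels
        target = next(c for c in rep["contrasts"] if c["label"] == "drought < control | week 4")
        # true drought effect is +4 sd, so "drought < control" should have low Pr
        assert target["pr"] < 0.5
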