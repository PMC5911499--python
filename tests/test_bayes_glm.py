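import numpy as np
import pandas as pd
import pytest
from scipy import stats

from threatdyn.bayes_glm import (
    MODEL_SPECS,
    DesignMatrix,
    ModelSpec,
    TransformMeta,
    build_design_matrix,
    condition_means,
    fit_model,
    posterior_predict,
)
from threatdyn.errors import ConvergenceError, ValidationError
from threatdyn.sampling import SamplerConfig
from threatdyn.synthetic import (
    SynthConfig,
    gen_covariates,
    gen_design,
    gen_outcomes,
    gen_survey,
)

FAST = SamplerConfig(chains=2, draws=300, warmup=300, seed=0, rhat_tol=None)


def covariate_table(n_participants, seed, truth_model="two_factor", **kw):
    cfg = SynthConfig(
        n_participants=n_participants, seed=seed, truth_model=truth_model, **kw
    )
    rng = np.random.default_rng(seed)
    table = gen_covariates(gen_design(cfg, rng), gen_survey(cfg, rng), cfg, rng)
    return gen_outcomes(table, cfg, rng)


class TestModelSpecs:
    def test_two_factor_columns(self):
        assert MODEL_SPECS["two_factor"].n_columns == 4

    def test_survey_based_columns(self):
        assert MODEL_SPECS["survey_based"].n_columns == 15

    def test_real_time_columns(self):
        # 1 + 7 + C(7,2) + C(7,3) = 64
        assert MODEL_SPECS["real_time"].n_columns == 64

    def test_nesting(self):
        tf = set(MODEL_SPECS["two_factor"].predictors)
        sb = set(MODEL_SPECS["survey_based"].predictors)
        rt = set(MODEL_SPECS["real_time"].predictors)
        assert tf < sb < rt

    def test_unknown_predictor_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec("bad", ("spoof", "wat"), 2)


class TestBuildDesignMatrix:
    def test_column_counts_and_labels(self):
        table, _ = covariate_table(6, seed=1)
        for name, spec in MODEL_SPECS.items():
            dm = build_design_matrix(table, spec)
            assert dm.X.shape == (36, spec.n_columns)
            assert dm.labels[0] == "intercept"
            assert len(dm.labels) == spec.n_columns

    def test_coding_conventions(self):
        table, _ = covariate_table(6, seed=2)
        dm = build_design_matrix(table, MODEL_SPECS["two_factor"])
        spoof_col = dm.X[:, dm.labels.index("spoof")]
        assert set(np.unique(spoof_col)) == {0.0, 1.0}
        auth_col = dm.X[:, dm.labels.index("auth")]
        assert set(np.unique(auth_col)) == {-1.0, 0.0, 1.0}
        inter = dm.X[:, dm.labels.index("spoof:auth")]
        np.testing.assert_allclose(inter, spoof_col * auth_col)

    def test_continuous_centering(self):
        table, _ = covariate_table(20, seed=3, truth_model="real_time")
        dm = build_design_matrix(table, MODEL_SPECS["real_time"])
        for name in ("knowledge", "familiarity", "auc", "se", "rt"):
            col = dm.X[:, dm.labels.index(name)]
            assert abs(col.mean()) < 1e-9
            assert col.std(ddof=0) == pytest.approx(0.5, abs=1e-9)  # 2-SD scaling

    def test_transform_projection_round_trip(self):
        table, _ = covariate_table(20, seed=4, truth_model="real_time")
        train, test = table.iloc[:90], table.iloc[90:]
        dm = build_design_matrix(train, MODEL_SPECS["real_time"])
        projected = build_design_matrix(test, MODEL_SPECS["real_time"], meta=dm.meta)
        assert projected.meta.centers == dm.meta.centers
        assert projected.meta.scales == dm.meta.scales
        # projecting the training rows reproduces the training matrix
        again = build_design_matrix(train, MODEL_SPECS["real_time"], meta=dm.meta)
        np.testing.assert_allclose(again.X, dm.X, atol=1e-12)

    def test_nonfinite_transform_flagged(self):
        table, _ = covariate_table(4, seed=5, truth_model="real_time")
        table.loc[0, "se_raw"] = 0.0
        table.loc[0, "se_log"] = -np.inf
        with pytest.raises(ValidationError):
            build_design_matrix(table, MODEL_SPECS["real_time"])
        dm = build_design_matrix(table, MODEL_SPECS["real_time"], na_action="drop")
        assert dm.X.shape[0] == len(table) - 1
        assert 0 not in dm.row_index


class TestFitModel:
    def test_recovers_two_factor_truth(self):
        table, truth = covariate_table(80, seed=6, sigma_u=1.03)
        spec = MODEL_SPECS["two_factor"]
        dm = build_design_matrix(table, spec)
        fit = fit_model(
            dm,
            table["accuracy"].to_numpy(float),
            table["participant_id"],
            spec,
            SamplerConfig(chains=2, draws=500, warmup=500, seed=1, rhat_tol=None),
        )
        flat = fit.beta_flat
        lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
        for label, value in (("intercept", 1.63), ("spoof", -1.69)):
            i = dm.labels.index(label)
            assert lo[i] <= value <= hi[i]
        assert np.all(fit.sigma_flat > 0)
        assert fit.beta.shape[:2] == fit.sigma_u.shape

    def test_diagnostics_present_for_all_parameters(self):
        table, _ = covariate_table(10, seed=7)
        spec = MODEL_SPECS["two_factor"]
        dm = build_design_matrix(table, spec)
        fit = fit_model(
            dm, table["accuracy"].to_numpy(float), table["participant_id"], spec, FAST
        )
        assert set(dm.labels) <= set(fit.diagnostics["rhat"])
        assert "sigma_u" in fit.diagnostics["rhat"]

    def test_nonconvergence_raises_with_parameters(self):
        table, _ = covariate_table(10, seed=8)
        spec = MODEL_SPECS["two_factor"]
        dm = build_design_matrix(table, spec)
        bad = SamplerConfig(
            chains=2, draws=40, warmup=5, seed=0, rhat_tol=1.01, max_treedepth=1
        )
        with pytest.raises(ConvergenceError) as err:
            fit_model(
                dm, table["accuracy"].to_numpy(float), table["participant_id"], spec, bad
            )
        assert err.value.parameters

    def test_binary_outcome_required(self):
        table, _ = covariate_table(4, seed=9)
        dm = build_design_matrix(table, MODEL_SPECS["two_factor"])
        with pytest.raises(ValidationError):
            fit_model(
                dm, np.full(len(table), 0.5), table["participant_id"],
                MODEL_SPECS["two_factor"], FAST,
            )

    def test_two_participants_required(self):
        table, _ = covariate_table(4, seed=10)
        sub = table[table["participant_id"] == "p0000"]
        dm = build_design_matrix(sub, MODEL_SPECS["two_factor"])
        with pytest.raises(ValidationError):
            fit_model(
                dm, sub["accuracy"].to_numpy(float), sub["participant_id"],
                MODEL_SPECS["two_factor"], FAST,
            )

    def test_prior_predictive_sanity(self):
        # no data: the intercept posterior reproduces its Student-t prior
        spec = MODEL_SPECS["two_factor"]
        dm = DesignMatrix(
            X=np.zeros((0, 1)),
            labels=["intercept"],
            meta=TransformMeta(centers={}, scales={}),
            row_index=np.array([], dtype=int),
        )
        fit = fit_model(
            dm, np.zeros(0), [], spec,
            SamplerConfig(chains=4, draws=1000, warmup=500, seed=2, rhat_tol=None),
        )
        draws = fit.beta_flat[:, 0]
        ks = stats.ks_1samp(draws, stats.t(df=3, scale=10).cdf)
        assert ks.statistic < 0.05

    def test_label_permutation_invariance(self):
        table, _ = covariate_table(30, seed=11)
        spec = MODEL_SPECS["two_factor"]
        y = table["accuracy"].to_numpy(float)
        dm = build_design_matrix(table, spec)
        cfg = SamplerConfig(chains=2, draws=500, warmup=400, seed=3, rhat_tol=None)
        fit_a = fit_model(dm, y, table["participant_id"], spec, cfg)
        # bijectively rename participants (reverses sort order)
        mapping = {
            pid: f"z{99 - int(pid[1:]):02d}"
            for pid in table["participant_id"].unique()
        }
        renamed = table["participant_id"].map(mapping)
        fit_b = fit_model(dm, y, renamed, spec, cfg)
        mcse = lambda f: f.beta_flat.std(0, ddof=1) / np.sqrt(200)  # conservative ESS
        tol = 3 * np.sqrt(mcse(fit_a) ** 2 + mcse(fit_b) ** 2)
        delta = np.abs(fit_a.beta_flat.mean(0) - fit_b.beta_flat.mean(0))
        assert np.all(delta <= tol + 0.05)

    def test_matches_ml_oracle_at_large_n(self):
        # sigma_u ~ 0 so an independent plain-ML fit is an unbiased oracle
        import statsmodels.api as sm

        table, _ = covariate_table(
            500, seed=12, sigma_u=1e-9, trials_per_participant=18
        )
        spec = MODEL_SPECS["two_factor"]
        dm = build_design_matrix(table, spec)
        y = table["accuracy"].to_numpy(float)
        fit = fit_model(
            dm, y, table["participant_id"], spec,
            SamplerConfig(chains=2, draws=600, warmup=500, seed=4, rhat_tol=None),
        )
        mle = sm.Logit(y, dm.X).fit(disp=0)
        means = fit.beta_flat.mean(axis=0)
        sds = fit.beta_flat.std(axis=0, ddof=1)
        mcse = sds / np.sqrt(150)  # conservative effective sample size
        assert np.all(np.abs(means - mle.params) <= 3 * mcse + 0.02)


class TestPosteriorPredict:
    @pytest.fixture(scope="class")
    def small_fit(self):
        table, _ = covariate_table(12, seed=13)
        spec = MODEL_SPECS["two_factor"]
        dm = build_design_matrix(table, spec)
        fit = fit_model(
            dm, table["accuracy"].to_numpy(float), table["participant_id"], spec, FAST
        )
        return table, dm, fit

    def test_intercept_only_row(self, small_fit):
        _, dm, fit = small_fit
        row = np.zeros((1, len(dm.labels)))
        row[0, dm.labels.index("intercept")] = 1.0
        probs = posterior_predict(fit, row, u_mode="zero")
        expected = 1 / (1 + np.exp(-fit.beta_flat[:, 0]))
        np.testing.assert_allclose(probs[:, 0], expected, atol=1e-12)

    def test_probabilities_in_unit_interval(self, small_fit):
        _, dm, fit = small_fit
        probs = posterior_predict(fit, dm.X, participant_ids=None)
        assert np.all((probs > 0) & (probs < 1))

    def test_known_participants_use_their_intercepts(self, small_fit):
        table, dm, fit = small_fit
        probs = posterior_predict(fit, dm.X[:1], participant_ids=["p0000"])
        j = fit.participant_index["p0000"]
        eta = fit.beta_flat @ dm.X[0] + fit.u_flat[:, j]
        np.testing.assert_allclose(probs[:, 0], 1 / (1 + np.exp(-eta)), atol=1e-12)

    def test_column_mismatch_rejected(self, small_fit):
        _, dm, fit = small_fit
        with pytest.raises(ValidationError):
            posterior_predict(fit, np.zeros((1, len(dm.labels) + 1)))

    def test_condition_means_decomposition(self, small_fit):
        table, dm, fit = small_fit
        cell = condition_means(
            fit, table, "non_spoof", "SV", rng=np.random.default_rng(9)
        )
        mask = (table["site_type"] == "non_spoof") & (table["auth_level"] == "SV")
        sub = build_design_matrix(table[mask], fit.spec, meta=fit.meta)
        probs = posterior_predict(
            fit, sub.X, participant_ids=None, rng=np.random.default_rng(9)
        )
        np.testing.assert_allclose(cell, probs.mean(axis=1), atol=1e-12)
        assert cell.shape == (fit.n_draws,)

    def test_perfect_separation_dominates(self):
        # all non-spoof trials correct: that cell's predicted mean is high
        table, _ = covariate_table(20, seed=14)
        table.loc[table["site_type"] == "non_spoof", "accuracy"] = 1
        spec = MODEL_SPECS["two_factor"]
        dm = build_design_matrix(table, spec)
        fit = fit_model(
            dm, table["accuracy"].to_numpy(float), table["participant_id"], spec, FAST
        )
        cell = condition_means(fit, table, "non_spoof", "SV")
        assert cell.mean() > 0.95


class TestConditionMeansMachinery:
    def test_spoof_difference_distribution(self):
        table, _ = covariate_table(20, seed=15, sigma_u=1.03)
        spec = MODEL_SPECS["two_factor"]
        dm = build_design_matrix(table, spec)
        fit = fit_model(
            dm, table["accuracy"].to_numpy(float), table["participant_id"], spec, FAST
        )
        rng = np.random.default_rng(3)
        non_spoof = np.mean(
            [condition_means(fit, table, "non_spoof", a, rng=rng) for a in ("PE", "SV", "EV")],
            axis=0,
        )
        spoof = np.mean(
            [condition_means(fit, table, "spoof", a, rng=rng) for a in ("PE", "SV", "EV")],
            axis=0,
        )
        diff = non_spoof - spoof
        assert diff.shape == (fit.n_draws,)
        # truth has spoof = -1.69: non-spoof cells must be credibly better
        assert np.percentile(diff, 2.5) > 0
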