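"""Season metrics and the crossed random-effects phenology models."""

import numpy as np
import pandas as pd
import pytest

from fruitscape import (FruitDateModel, FruitProductionModel, PhenologyRecord,
                        bootstrap_variance_pvalue, compute_season_metrics,
                        fit_descriptive_lmm, fit_model_I, fit_model_II,
                        records_to_fruit_dates)
from fruitscape.glmm import CrossedLMM, CrossedPoissonGLMM, NonIdentifiableError


def _recs(rows):
    return [PhenologyRecord(t, s, d, c) for t, s, d, c in rows]


class TestSeasonMetrics:
    def test_hand_computed_equal_weights(self):
        m = compute_season_metrics(_recs([("t", "s", 200.0, 1), ("t", "s", 210.0, 1),
                                          ("t", "s", 220.0, 1)]))[0]
        assert m.production == 3
        assert m.peak == pytest.approx(210.0)
        assert m.duration == pytest.approx(40.0)       # SD = 10, x4

    def test_hand_computed_weighted(self):
        m = compute_season_metrics(_recs([("t", "s", 200.0, 2), ("t", "s", 220.0, 2)]))[0]
        assert m.peak == pytest.approx(210.0)
        # four fruits at {200,200,220,220}: SS = 400, var = 400/3
        assert m.duration == pytest.approx(4 * np.sqrt(400.0 / 3.0))

    def test_degenerate_cells(self):
        out = compute_season_metrics(_recs([("a", "s", 150.0, 1), ("b", "s", 100.0, 0)]))
        by_tree = {m.tree_id: m for m in out}
        assert by_tree["a"].production == 1
        assert by_tree["a"].peak == 150.0
        assert by_tree["a"].duration is None
        assert by_tree["b"].production == 0
        assert by_tree["b"].peak is None

    def test_shift_and_scale_equivariance(self, rng):
        rows = [("t", "s", float(d), int(c)) for d, c in
                zip(rng.uniform(100, 300, 8), rng.integers(1, 6, 8))]
        base = compute_season_metrics(_recs(rows))[0]
        shifted = compute_season_metrics(
            _recs([(t, s, d + 25.0, c) for t, s, d, c in rows]))[0]
        assert shifted.peak == pytest.approx(base.peak + 25.0)
        assert shifted.duration == pytest.approx(base.duration)
        assert shifted.production == base.production
        scaled = compute_season_metrics(
            _recs([(t, s, d * 0.5, c) for t, s, d, c in rows]))[0]
        assert scaled.duration == pytest.approx(base.duration * 0.5)

    def test_expansion_to_fruit_dates(self):
        df = records_to_fruit_dates(_recs([("t", "s", 200.0, 3), ("t", "s", 210.0, 0)]))
        assert len(df) == 3
        assert set(df["day"]) == {200.0}


@pytest.fixture(scope="module")
def lme4_oracle_data():
    """Small crossed datasets whose reference fits were computed with R lme4
    (lmer/glmer, Laplace); the reference estimates are frozen below."""
    rng = np.random.default_rng(42)
    nt, ns, m = 8, 6, 4
    w = 10 * rng.standard_normal(nt)
    z = 5 * rng.standard_normal(ns)
    tree = np.repeat(np.arange(nt), ns * m)
    season = np.tile(np.repeat(np.arange(ns), m), nt)
    y = 200 + w[tree] + z[season] + 15 * rng.standard_normal(tree.size)
    dbh = rng.uniform(500, 1500, nt)
    u = 0.5 * rng.standard_normal(nt)
    v = 0.8 * rng.standard_normal(ns)
    ti = np.repeat(np.arange(nt), ns)
    sj = np.tile(np.arange(ns), nt)
    yc = rng.poisson(np.exp(-0.12 + 1.5e-3 * dbh[ti] + u[ti] + v[sj]))
    return dict(y=y, tree=tree, season=season, yc=yc, dbh=dbh, ti=ti, sj=sj)


class TestAgainstLme4:
    def test_reml_crossed_lmm_matches_lmer(self, lme4_oracle_data):
        d = lme4_oracle_data
        res = CrossedLMM(d["y"], np.ones((d["y"].size, 1)),
                         {"tree": d["tree"], "season": d["season"]}).fit(reml=True)
        assert res.beta[0] == pytest.approx(198.1366, abs=1e-3)
        assert res.beta_se[0] == pytest.approx(3.513258, abs=1e-3)
        assert res.sd_components[0] == pytest.approx(9.389293, abs=2e-3)
        assert res.sd_components[1] == pytest.approx(1.494435, abs=2e-3)
        assert res.sigma_resid == pytest.approx(13.511982, abs=1e-3)
        assert res.loglik == pytest.approx(-780.6199, abs=1e-3)

    def test_laplace_poisson_glmm_matches_glmer(self, lme4_oracle_data):
        d = lme4_oracle_data
        X = np.column_stack([np.ones(d["ti"].size), d["dbh"][d["ti"]]])
        res = CrossedPoissonGLMM(d["yc"], X,
                                 {"tree": d["ti"], "season": d["sj"]}).fit()
        assert res.beta[0] == pytest.approx(-1.048518, abs=5e-3)
        assert res.beta[1] == pytest.approx(0.002498726, abs=5e-6)
        assert res.sd_components[0] == pytest.approx(0.2349243, abs=2e-3)
        assert res.sd_components[1] == pytest.approx(0.2490898, abs=2e-3)
        assert res.loglik == pytest.approx(-116.3001, abs=2e-3)


class TestModelII:
    def test_zero_random_effects_reduce_to_sample_moments(self, rng):
        """With no true tree/season effects the variance components collapse
        toward the boundary and (c3, sigma) track the plain sample moments."""
        nt, ns, m = 10, 8, 30
        tree = np.repeat([f"t{i}" for i in range(nt)], ns * m)
        season = np.tile(np.repeat([f"s{j}" for j in range(ns)], m), nt)
        day = 209.3 + 19.62 * rng.standard_normal(nt * ns * m)
        fit = fit_model_II(pd.DataFrame({"tree_id": tree, "season_id": season,
                                         "day": day}))
        assert fit.sd_w < 2.0 and fit.sd_z < 2.0   # boundary noise scale
        assert fit.c3 == pytest.approx(day.mean(), abs=1.0)
        assert fit.sigma_resid == pytest.approx(day.std(ddof=1), rel=0.02)

    def test_weekly_binning_shifts_sigma_less_than_bin_sd(self, rng):
        """Binning fall days to weekly visits perturbs the residual SD by
        less than the binning SD sqrt(49/12) ~ 2.02 d."""
        nt, ns, m = 20, 10, 20
        w = 13.31 * rng.standard_normal(nt)
        z = 8.51 * rng.standard_normal(ns)
        tree = np.repeat([f"t{i}" for i in range(nt)], ns * m)
        ti = np.repeat(np.arange(nt), ns * m)
        season = np.tile(np.repeat([f"s{j}" for j in range(ns)], m), nt)
        sj = np.tile(np.repeat(np.arange(ns), m), nt)
        day = 209.3 + w[ti] + z[sj] + 19.62 * rng.standard_normal(nt * ns * m)
        binned = np.floor(day / 7.0) * 7.0 + 3.5
        f1 = fit_model_II(pd.DataFrame({"tree_id": tree, "season_id": season, "day": day}))
        f2 = fit_model_II(pd.DataFrame({"tree_id": tree, "season_id": season, "day": binned}))
        assert abs(f1.sigma_resid - f2.sigma_resid) < np.sqrt(49.0 / 12.0)

    def test_single_cell_not_identifiable(self):
        df = pd.DataFrame({"tree_id": ["a"] * 5, "season_id": ["s"] * 5,
                           "day": [200.0, 201, 202, 203, 204]})
        with pytest.raises(NonIdentifiableError):
            FruitDateModel(df)

    def test_one_observation_per_cell_not_identifiable(self):
        df = pd.DataFrame({"tree_id": ["a", "a", "b", "b"],
                           "season_id": ["s1", "s2", "s1", "s2"],
                           "day": [200.0, 205, 210, 215]})
        with pytest.raises(NonIdentifiableError):
            FruitDateModel(df)


class TestModelI:
    def test_zero_variance_truth_reduces_to_poisson_glm(self, rng):
        import statsmodels.api as sm
        nt, ns = 30, 12
        dbh = {f"t{i}": float(d) for i, d in enumerate(rng.uniform(500, 1500, nt))}
        rows = []
        for i in range(nt):
            lam = np.exp(-0.12 + 1.5e-3 * dbh[f"t{i}"])
            for j in range(ns):
                rows.append((f"t{i}", f"s{j}", int(rng.poisson(lam))))
        totals = pd.DataFrame(rows, columns=["tree_id", "season_id", "production"])
        fit = fit_model_I(totals, dbh)
        d = totals["tree_id"].map(dbh).to_numpy()
        glm = sm.GLM(totals["production"].to_numpy(), sm.add_constant(d),
                     family=sm.families.Poisson()).fit()
        # components collapse to boundary noise; the mixed fit offers no
        # significant likelihood improvement over the plain GLM and the
        # fixed effects agree
        assert fit.sd_u < 0.15 and fit.sd_v < 0.15
        assert 2.0 * (fit.loglik - glm.llf) < 4.0
        assert fit.c1 == pytest.approx(glm.params[0], abs=0.05)
        assert fit.c2 == pytest.approx(glm.params[1], abs=5e-5)

    def test_all_zero_counts_rejected(self):
        totals = pd.DataFrame({"tree_id": ["a", "b", "c"] * 3,
                               "season_id": np.repeat(["s1", "s2", "s3"], 3),
                               "production": 0})
        with pytest.raises(ValueError):
            fit_model_I(totals, {"a": 500.0, "b": 600.0, "c": 700.0})

    def test_non_integer_totals_rejected(self):
        totals = pd.DataFrame({"tree_id": ["a", "b", "c"] * 3,
                               "season_id": np.repeat(["s1", "s2", "s3"], 3),
                               "production": 1.5})
        with pytest.raises(ValueError):
            FruitProductionModel(totals, {"a": 500.0, "b": 600.0, "c": 700.0})


class TestDescriptiveModels:
    @staticmethod
    def _metrics_from(rng, nt=25, ns=12, sd_tree=15.49, sd_season=5.04, resid=8.0):
        w = sd_tree * rng.standard_normal(nt)
        z = sd_season * rng.standard_normal(ns)
        from fruitscape.phenology import SeasonMetrics
        return [SeasonMetrics(f"t{i}", f"s{j}", 10,
                              209.3 + w[i] + z[j] + resid * rng.standard_normal(), 60.0)
                for i in range(nt) for j in range(ns)]

    def test_zero_variance_data(self):
        from fruitscape.phenology import SeasonMetrics
        ms = [SeasonMetrics(f"t{i}", f"s{j}", 5, 209.3, 59.3)
              for i in range(4) for j in range(4)]
        fit = fit_descriptive_lmm(ms, "peak")
        assert fit.intercept == pytest.approx(209.3)
        assert fit.sd_tree == pytest.approx(0.0, abs=1e-6)
        assert fit.sd_season == pytest.approx(0.0, abs=1e-6)

    def test_permuting_tree_labels_destroys_tree_component(self, rng):
        ms = self._metrics_from(rng)
        fit = fit_descriptive_lmm(ms, "peak")
        assert fit.sd_tree > 10.0
        # permute tree labels independently within each season
        by_season = {}
        permuted = []
        from fruitscape.phenology import SeasonMetrics
        for m in ms:
            by_season.setdefault(m.season_id, []).append(m)
        for sid, group in by_season.items():
            labels = [m.tree_id for m in group]
            rng.shuffle(labels)
            permuted += [SeasonMetrics(l, m.season_id, m.production, m.peak, m.duration)
                         for l, m in zip(labels, group)]
        fit2 = fit_descriptive_lmm(permuted, "peak")
        assert fit2.sd_tree < 0.5 * fit.sd_tree
        assert fit2.sd_tree < 5.0

    def test_production_variant_delegates_to_model_I(self, rng):
        from fruitscape.phenology import SeasonMetrics
        dbh = {f"t{i}": float(d) for i, d in enumerate(rng.uniform(500, 1500, 10))}
        ms = [SeasonMetrics(f"t{i}", f"s{j}", int(rng.poisson(3.0)) , None, None)
              for i in range(10) for j in range(8)]
        fit = fit_descriptive_lmm(ms, "production", dbh=dbh)
        assert fit.metric == "production"
        assert np.isfinite(fit.intercept)

    def test_recovery_of_peak_model_parameters(self, rng):
        """Intercept and variance components recovered within 15% on a large
        crossed design (truth: 209.3 / 15.49 / 5.04 / resid 8)."""
        ms = self._metrics_from(rng, nt=200, ns=30)
        fit = fit_descriptive_lmm(ms, "peak")
        assert fit.intercept == pytest.approx(209.3, rel=0.05)
        assert fit.sd_tree == pytest.approx(15.49, rel=0.15)
        assert fit.sd_season == pytest.approx(5.04, rel=0.30)  # only 30 seasons
        assert fit.sd_resid == pytest.approx(8.0, rel=0.15)


class TestBootstrap:
    def test_pvalue_bounded_in_unit_interval(self, rng):
        nt, ns, m = 8, 6, 3
        z = 5 * rng.standard_normal(ns)
        tree = np.repeat(np.arange(nt), ns * m)
        season = np.tile(np.repeat(np.arange(ns), m), nt)
        y = 200 + z[season] + 10 * rng.standard_normal(nt * ns * m)
        lmm = CrossedLMM(y, np.ones((y.size, 1)), {"tree": tree, "season": season})
        p = bootstrap_variance_pvalue(lmm, "tree", n_boot=49, rng=rng)
        assert 0.0 < p <= 1.0

    def test_power_against_strong_tree_effect(self, rng):
        """sd_tree = 15 on residual 5: the tree component must be detected."""
        nt, ns, m = 12, 8, 4
        w = 15 * rng.standard_normal(nt)
        tree = np.repeat(np.arange(nt), ns * m)
        season = np.tile(np.repeat(np.arange(ns), m), nt)
        y = 200 + w[tree] + 5 * rng.standard_normal(nt * ns * m)
        lmm = CrossedLMM(y, np.ones((y.size, 1)), {"tree": tree, "season": season})
        p = bootstrap_variance_pvalue(lmm, "tree", n_boot=199, rng=rng)
        assert p < 0.01

    def test_fixed_effect_bootstrap_on_poisson_model(self, rng):
        """The DBH effect test on model I runs through the GLMM bootstrap
        path and detects a strong true slope."""
        nt, ns = 15, 8
        dbh = {f"t{i:02d}": float(d) for i, d in enumerate(rng.uniform(500, 1500, nt))}
        rows = []
        for i in range(nt):
            for j in range(ns):
                lam = np.exp(-0.12 + 2e-3 * dbh[f"t{i:02d}"])
                rows.append((f"t{i:02d}", f"s{j}", int(rng.poisson(lam))))
        totals = pd.DataFrame(rows, columns=["tree_id", "season_id", "production"])
        model = FruitProductionModel(totals, dbh)
        p = bootstrap_variance_pvalue(model, "fixed", n_boot=19, rng=rng)
        assert p <= 0.05

    def test_unknown_component_rejected(self, rng):
        y = rng.standard_normal(40)
        lmm = CrossedLMM(y, np.ones((40, 1)),
                         {"tree": np.repeat(np.arange(8), 5),
                          "season": np.tile(np.arange(5), 8)})
        with pytest.raises(ValueError):
            bootstrap_variance_pvalue(lmm, "plot", n_boot=9, rng=rng)
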