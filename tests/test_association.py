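import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from somnomorph.association import (
    EXPLORATIVE_PSG_VARIABLES,
    AnalysisPlan,
    PlanItem,
    explorative_plan,
    fdr_adjust,
    fisher_mean_correlation,
    fit_univariate,
    hypothesis_plan,
    icv_age_correlation,
    icv_sex_ttest,
    residual_adjust,
    run_plan,
)
from somnomorph.morphometry import MORPH_COLUMNS
from somnomorph.synthetic import SimConfig, generate_covariates, generate_morphometry


def _ols_oracle(y, X):
    """Independent normal-equations OLS for the coefficient of column 1."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1])
    t = beta[1] / se
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return float(beta[1]), float(t), df, float(p)


def _bh_oracle(p):
    """Brute-force tail-min BH: padj(i) = min_{j>=i} min(m p(j)/j, 1) on sorted p."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(m * sorted_p[j] / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestFitUnivariate:
    def test_exact_linear_relation(self, rng):
        x = rng.standard_normal(30)
        res = fit_univariate(2.0 * x, x, None)
        assert res.b == pytest.approx(2.0, abs=1e-9)
        assert res.p < 1e-12
        assert abs(res.t) > 1e12 or np.isinf(res.t)

    def test_df_is_33_at_n_38_with_three_covariates(self, rng):
        y = rng.standard_normal(38)
        x = rng.standard_normal(38)
        res = fit_univariate(y, x, rng.standard_normal((38, 3)))
        assert res.df == 33 and res.n == 38

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            k = int(rng.integers(0, 4))
            x = rng.standard_normal(n)
            cov = rng.standard_normal((n, k))
            y = (0.7 * x + cov @ rng.standard_normal(k)
                 + rng.standard_normal(n) + rng.normal(0, 2))
            res = fit_univariate(y, x, cov if k else None)
            b, t, df, p = _ols_oracle(y, np.column_stack([np.ones(n), x, cov]))
            assert res.b == pytest.approx(b, rel=1e-8)
            assert res.t == pytest.approx(t, rel=1e-8)
            assert res.df == df
            assert res.p == pytest.approx(p, rel=1e-8, abs=1e-300)

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            fit_univariate(rng.standard_normal(10), rng.standard_normal(9), None)
        with pytest.raises(ValueError, match="observations"):
            fit_univariate(np.ones(2), np.arange(2.0), None)
        x = rng.standard_normal(20)
        with pytest.raises(ValueError, match="collinear"):
            fit_univariate(rng.standard_normal(20), x, 3.0 * x)

    def test_confidence_interval_coverage(self):
        covered = 0
        n_rep = 200
        for rep in range(n_rep):
            r = np.random.default_rng(5000 + rep)
            x = r.standard_normal(38)
            cov = r.standard_normal((38, 3))
            y = 0.5 * x + cov @ np.array([0.2, -0.3, 0.1]) + r.standard_normal(38)
            res = fit_univariate(y, x, cov)
            half = scipy.stats.t.ppf(0.975, res.df) * abs(res.b / res.t)
            covered += abs(res.b - 0.5) <= half
        assert 0.90 <= covered / n_rep <= 0.99


class TestFdrAdjust:
    def test_hand_example(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_brute_force_oracle_random(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 12)))
            assert np.allclose(fdr_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_brute_force_oracle_with_ties(self):
        p = np.array([0.01, 0.01, 0.5, 0.5, 0.03, 1.0])
        assert np.allclose(fdr_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_all_permutations_consistent(self, rng):
        p = rng.uniform(size=6)
        base = dict(zip(p, fdr_adjust(p)))
        for perm in itertools.permutations(p):
            adj = fdr_adjust(list(perm))
            for raw, a in zip(perm, adj):
                assert a == pytest.approx(base[raw], abs=1e-12)

    def test_monotone_and_bounded(self, rng):
        p = np.sort(rng.uniform(size=30))
        adj = fdr_adjust(p)
        assert np.all(np.diff(adj) >= -1e-15)
        assert np.all((adj >= p - 1e-15) & (adj <= 1.0))

    def test_single_value_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            fdr_adjust([])
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            fdr_adjust([0.5, float("nan")])


class TestPlans:
    def test_hypothesis_plan_has_14_items(self):
        plan = hypothesis_plan()
        assert plan.mode == "hypothesis"
        assert len(plan) == 14
        # 2 items drop the ICV covariate and restrict to age < 40
        special = [i for i in plan.items if i.age_max is not None]
        assert len(special) == 2
        assert all(i.covariates == ("age", "sex") for i in special)
        assert all(i.independent == "CC_Anterior" for i in special)
        deps = {i.dependent for i in plan.items}
        assert deps == {"n2_delta1", "n2_delta2", "tst_min"}

    def test_explorative_plan_has_6786_items(self):
        plan = explorative_plan()
        assert plan.mode == "explorative"
        assert len(plan) == 39 * 174 == 6786
        assert len(EXPLORATIVE_PSG_VARIABLES) == 39
        assert len({i.dependent for i in plan.items}) == 39
        assert len({i.independent for i in plan.items}) == 174

    def test_invalid_mode(self):
        with pytest.raises(ValueError, match="mode"):
            AnalysisPlan(mode="fishing")


@pytest.fixture
def study_tables():
    cfg = SimConfig(n_subjects=38, seed=11)
    covariates = generate_covariates(cfg, np.random.default_rng(11))
    morph = generate_morphometry(cfg, covariates, rng=np.random.default_rng(12))
    morph = morph.join(covariates)
    r = np.random.default_rng(13)
    psg = pd.DataFrame(
        {v: r.standard_normal(38) for v in EXPLORATIVE_PSG_VARIABLES},
        index=covariates.index,
    )
    return psg, morph


class TestRunPlan:
    def test_hypothesis_results(self, study_tables):
        psg, morph = study_tables
        results = run_plan(hypothesis_plan(), psg, morph)
        assert len(results) == 14
        full = results[results["n"] == 38]
        assert (full["df"] == 33).all()
        assert results["p"].between(0, 1).all()
        assert "p_fdr" not in results.columns
        # the age-restricted items use fewer subjects and one fewer covariate
        young = results[results["n"] < 38]
        assert len(young) == 2
        assert (young["df"] == young["n"] - 4).all()

    def test_missing_variable_raises_before_fitting(self, study_tables):
        psg, morph = study_tables
        with pytest.raises(KeyError, match="no_such_var"):
            run_plan(
                AnalysisPlan("hypothesis", [PlanItem("no_such_var", "CC_Anterior")]),
                psg, morph,
            )

    def test_disjoint_subjects_raise(self, study_tables):
        psg, morph = study_tables
        psg2 = psg.copy()
        psg2.index = ["x" + s for s in psg.index]
        with pytest.raises(ValueError, match="no subject ids"):
            run_plan(hypothesis_plan(), psg2, morph)

    def test_nan_dependent_drops_subjects(self, study_tables):
        psg, morph = study_tables
        psg = psg.copy()
        psg.loc[psg.index[:3], "n2_delta1"] = np.nan
        results = run_plan(hypothesis_plan(), psg, morph)
        # standard (icv/age/sex-adjusted) items for this dependent: df = n - 5
        d1 = results[(results["dependent"] == "n2_delta1")
                     & (results["df"] == results["n"] - 5)]
        assert len(d1) == 5
        assert (d1["n"] == 35).all()
        assert (d1["df"] == 30).all()

    def test_too_few_subjects_yield_nan_row(self, study_tables):
        psg, morph = study_tables
        plan = AnalysisPlan("hypothesis", [PlanItem("n2_delta1", "CC_Anterior")])
        with pytest.warns(UserWarning, match="complete"):
            results = run_plan(plan, psg.iloc[:4], morph.iloc[:4])
        assert len(results) == 1
        assert np.isnan(results.loc[0, "b"]) and np.isnan(results.loc[0, "p"])

    def test_explorative_fdr_within_dependent(self, study_tables):
        psg, morph = study_tables
        deps = ("tst_min", "rem_beta2")
        plan = explorative_plan(psg_variables=deps)
        results = run_plan(plan, psg, morph)
        assert len(results) == 2 * 174
        for dep in deps:
            grp = results[results["dependent"] == dep]
            assert np.allclose(grp["p_fdr"].to_numpy(),
                               fdr_adjust(grp["p"].to_numpy()))

    def test_null_data_fdr_rarely_discovers(self):
        # no planted effects: with BH at q=.05 within each dependent's 174
        # tests, the fraction of (replicate, dependent) families with any
        # discovery should stay well under 15%
        deps = EXPLORATIVE_PSG_VARIABLES[:5]
        plan = explorative_plan(psg_variables=deps)
        families = families_hit = 0
        for rep in range(20):
            cfg = SimConfig(n_subjects=38, seed=300 + rep)
            covariates = generate_covariates(cfg, np.random.default_rng(300 + rep))
            morph = generate_morphometry(
                cfg, covariates, rng=np.random.default_rng(600 + rep)
            ).join(covariates)
            r = np.random.default_rng(900 + rep)
            psg = pd.DataFrame({v: r.standard_normal(38) for v in deps},
                               index=covariates.index)
            results = run_plan(plan, psg, morph)
            for _, grp in results.groupby("dependent"):
                families += 1
                families_hit += bool((grp["p_fdr"] < 0.05).any())
        assert families == 100
        assert families_hit / families <= 0.15


class TestAdjustmentHelpers:
    def test_residual_adjust_preserves_mean(self, rng):
        values = rng.standard_normal(40) + 3.0
        cov = rng.standard_normal((40, 3))
        adj = residual_adjust(values, cov)
        assert adj.mean() == pytest.approx(values.mean(), abs=1e-10)

    def test_residuals_orthogonal_to_covariates(self, rng):
        values = rng.standard_normal(40)
        cov = rng.standard_normal((40, 2))
        adj = residual_adjust(values, cov) - values.mean()
        for j in range(2):
            assert abs(np.corrcoef(adj, cov[:, j])[0, 1]) < 1e-9

    def test_orthogonal_covariate_leaves_values_unchanged(self, rng):
        values = rng.standard_normal(40)
        raw = rng.standard_normal(40)
        # project out the span of [1, values] so OLS finds exactly zero effect
        design = np.column_stack([np.ones(40), values])
        z = raw - design @ np.linalg.lstsq(design, raw, rcond=None)[0]
        adj = residual_adjust(values, z)
        assert np.allclose(adj, values, atol=1e-9)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            residual_adjust(rng.standard_normal(10), rng.standard_normal((9, 2)))

    def test_fisher_mean_correlation(self):
        assert fisher_mean_correlation([0.3]) == pytest.approx(0.3)
        assert fisher_mean_correlation([0.5, -0.5]) == pytest.approx(0.0, abs=1e-15)
        # tanh((atanh(.3) + atanh(.6)) / 2) = tanh(0.501326...) = 0.463165
        assert fisher_mean_correlation([0.3, 0.6]) == pytest.approx(0.463165, abs=5e-6)
        with pytest.raises(ValueError):
            fisher_mean_correlation([0.5, 1.0])

    def test_icv_descriptives(self, study_tables):
        _, morph = study_tables
        r, p = icv_age_correlation(morph)
        assert -1 <= r <= 1 and 0 <= p <= 1
        t, df, p2 = icv_sex_ttest(morph)
        assert df == 38 - 2
        assert 0 <= p2 <= 1
        # generator gives men larger ICV on average
        assert t != 0.0
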