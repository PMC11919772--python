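import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methvar import association as assoc
from methvar import sim


# ---------------------------------------------------------------------------
# brute-force oracles, written from first principles and independent of the
# vectorised implementations they check

def oracle_levene(g1, g2, center=np.median):
    """One-way ANOVA on absolute deviations from the group centre."""
    z1 = np.abs(np.asarray(g1) - center(g1))
    z2 = np.abs(np.asarray(g2) - center(g2))
    n1, n2 = len(z1), len(z2)
    n, k = n1 + n2, 2
    zbar = (z1.sum() + z2.sum()) / n
    ss_between = n1 * (z1.mean() - zbar) ** 2 + n2 * (z2.mean() - zbar) ** 2
    ss_within = ((z1 - z1.mean()) ** 2).sum() + ((z2 - z2.mean()) ** 2).sum()
    w = (n - k) / (k - 1) * ss_between / ss_within
    return w, stats.f.sf(w, k - 1, n - k)


def oracle_bartlett(g1, g2):
    n1, n2 = len(g1), len(g2)
    n, k = n1 + n2, 2
    v1, v2 = np.var(g1, ddof=1), np.var(g2, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n - k)
    num = (n - k) * np.log(sp2) - (n1 - 1) * np.log(v1) - (n2 - 1) * np.log(v2)
    c = 1 + (1 / (n1 - 1) + 1 / (n2 - 1) - 1 / (n - k)) / (3 * (k - 1))
    t = num / c
    return t, stats.chi2.sf(t, k - 1)


def oracle_fligner(g1, g2):
    d = np.concatenate([np.abs(np.asarray(g1) - np.median(g1)),
                        np.abs(np.asarray(g2) - np.median(g2))])
    n1, n2 = len(g1), len(g2)
    n = n1 + n2
    ranks = stats.rankdata(d)
    a = stats.norm.ppf(0.5 + ranks / (2 * (n + 1)))
    v = np.var(a, ddof=1)
    abar = a.mean()
    x2 = (n1 * (a[:n1].mean() - abar) ** 2
          + n2 * (a[n1:].mean() - abar) ** 2) / v
    return x2, stats.chi2.sf(x2, 1)


def oracle_ols(x, y):
    """Normal-equations OLS: coefficients and standard errors."""
    xtx_inv = np.linalg.inv(x.T @ x)
    b = xtx_inv @ x.T @ y
    resid = y - x @ b
    s2 = resid @ resid / (len(y) - x.shape[1])
    se = np.sqrt(s2 * np.diag(xtx_inv))
    return b, se


# ---------------------------------------------------------------------------

class TestResidualize:
    def test_intercept_only_centers(self, rng):
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, (5, 12)),
                            index=sim.probe_ids(5),
                            columns=[f"s{i}" for i in range(12)])
        sheet = pd.DataFrame({"diagnosis": "control"}, index=beta.columns)
        spec = assoc.CovariateSpec(numeric=(), categorical=(),
                                   cell_proportion_prefix="cell_prop_")
        resid = assoc.residualize(beta, sheet, spec)
        expected = beta.sub(beta.mean(axis=1), axis=0)
        np.testing.assert_allclose(resid.to_numpy(), expected.to_numpy(),
                                   atol=1e-12)

    def test_residuals_orthogonal_to_design(self, small_cohort):
        resid = assoc.residualize(small_cohort["beta"],
                                  small_cohort["samplesheet"])
        design = assoc.build_design(small_cohort["samplesheet"])
        inner = resid.to_numpy() @ design.loc[resid.columns].to_numpy()
        assert np.abs(inner).max() < 1e-8

    def test_row_means_near_zero(self, small_cohort):
        resid = assoc.residualize(small_cohort["beta"],
                                  small_cohort["samplesheet"])
        assert np.abs(resid.mean(axis=1)).max() < 1e-10

    def test_planted_age_slope_removed(self):
        cfg = sim.SimConfig(n_cohorts=1, n_cases=100, n_controls=100,
                            n_probes=50, age_slope_sd=0.05, seed=13)
        beta, _, _, sheet, _ = sim.generate_cohort(cfg, 0)
        resid = assoc.residualize(beta, sheet)
        age = sheet.loc[resid.columns, "horvath_age"].to_numpy()
        corrs = [np.corrcoef(row, age)[0, 1] for row in resid.to_numpy()]
        assert np.abs(corrs).max() < 1e-6

    def test_rank_deficient_design_names_columns(self, small_cohort):
        sheet = small_cohort["samplesheet"].copy()
        sheet["age_copy"] = sheet["horvath_age"]
        spec = assoc.CovariateSpec(numeric=("horvath_age", "age_copy"),
                                   categorical=())
        with pytest.raises(ValueError, match="age_copy|horvath_age"):
            assoc.residualize(small_cohort["beta"], sheet, spec)


class TestLevene:
    def test_identical_groups(self):
        g = np.array([1.0, 2, 3, 4, 5])
        w, p, z = assoc.levene_test(g, g)
        assert w[0] == pytest.approx(0.0)
        assert p[0] == pytest.approx(1.0)
        assert z[0] == pytest.approx(0.0)

    def test_matches_bruteforce_oracle(self, rng):
        g1 = rng.normal(0, 2, 8)
        g2 = rng.normal(0, 1, 8)
        w, p, _ = assoc.levene_test(g1, g2)
        w_ref, p_ref = oracle_levene(g1, g2)
        assert w[0] == pytest.approx(w_ref, rel=1e-10)
        assert p[0] == pytest.approx(p_ref, rel=1e-10)

    def test_mean_center_matches_oracle(self, rng):
        g1, g2 = rng.normal(0, 2, 10), rng.normal(0, 1, 12)
        w, p, _ = assoc.levene_test(g1, g2, center="mean")
        w_ref, p_ref = oracle_levene(g1, g2, center=np.mean)
        assert w[0] == pytest.approx(w_ref, rel=1e-10)

    def test_matches_scipy(self, rng):
        case = rng.normal(0, 1.5, (6, 15))
        ctrl = rng.normal(0, 1.0, (6, 18))
        w, p, _ = assoc.levene_test(case, ctrl)
        for i in range(6):
            w_ref, p_ref = stats.levene(case[i], ctrl[i], center="median")
            assert w[i] == pytest.approx(w_ref, rel=1e-12)
            assert p[i] == pytest.approx(p_ref, rel=1e-12)

    def test_group_swap_flips_sign(self, rng):
        g1, g2 = rng.normal(0, 2, 10), rng.normal(0, 1, 10)
        _, p1, z1 = assoc.levene_test(g1, g2)
        _, p2, z2 = assoc.levene_test(g2, g1)
        assert z1[0] == pytest.approx(-z2[0])
        assert p1[0] == pytest.approx(p2[0])

    def test_degenerate_dispersion_gives_nan(self):
        g = np.full(5, 3.0)
        w, p, z = assoc.levene_test(g, g)
        assert np.isnan(w[0]) and np.isnan(z[0])

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            assoc.levene_test(np.array([1.0]), np.array([1.0, 2.0]))


class TestBartlett:
    def test_equal_variances(self):
        g1 = np.array([1.0, 2, 3, 4, 5])
        g2 = g1 + 10.0
        t, p, z = assoc.bartlett_test(g1, g2)
        assert t[0] == pytest.approx(0.0, abs=1e-12)
        assert p[0] == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self, rng):
        g1 = rng.normal(0, 3, 9)
        g2 = rng.normal(0, 1, 11)
        t, p, _ = assoc.bartlett_test(g1, g2)
        t_ref, p_ref = oracle_bartlett(g1, g2)
        assert t[0] == pytest.approx(t_ref, rel=1e-10)
        assert p[0] == pytest.approx(p_ref, rel=1e-10)

    def test_scale_invariance(self, rng):
        g1, g2 = rng.normal(0, 2, 10), rng.normal(0, 1, 10)
        t1, _, _ = assoc.bartlett_test(g1, g2)
        t2, _, _ = assoc.bartlett_test(7.3 * g1, 7.3 * g2)
        assert t1[0] == pytest.approx(t2[0], rel=1e-10)

    def test_sign_follows_variance_order(self, rng):
        g1 = rng.normal(0, 5, 30)   # cases more dispersed
        g2 = rng.normal(0, 1, 30)
        _, _, z = assoc.bartlett_test(g1, g2)
        assert z[0] > 0

    def test_zero_variance_gives_nan(self):
        t, p, z = assoc.bartlett_test(np.full(5, 2.0),
                                      np.array([1.0, 2, 3, 4, 5]))
        assert np.isnan(t[0])


class TestFlignerKilleen:
    def test_identical_groups(self):
        g = np.array([1.0, 2, 3, 4, 5])
        x2, p, z = assoc.fligner_killeen_test(g, g)
        assert x2[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        g1 = rng.normal(0, 2, 12)
        g2 = rng.normal(0, 1, 9)
        x2, p, _ = assoc.fligner_killeen_test(g1, g2)
        x2_ref, p_ref = oracle_fligner(g1, g2)
        assert x2[0] == pytest.approx(x2_ref, rel=1e-10)
        assert p[0] == pytest.approx(p_ref, rel=1e-10)

    def test_matches_scipy(self, rng):
        g1, g2 = rng.normal(0, 2, 20), rng.normal(0, 1, 25)
        x2, p, _ = assoc.fligner_killeen_test(g1, g2)
        x2_ref, p_ref = stats.fligner(g1, g2)
        assert x2[0] == pytest.approx(x2_ref, rel=1e-10)
        assert p[0] == pytest.approx(p_ref, rel=1e-10)

    def test_depends_only_on_deviation_ranks(self, rng):
        # a monotone transform of one group's deviations that preserves the
        # pooled rank order leaves the statistic unchanged
        g1 = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        g2 = np.array([-4.0, -3.0, 0.0, 3.0, 4.0])
        x2a, _, _ = assoc.fligner_killeen_test(g1, g2)
        x2b, _, _ = assoc.fligner_killeen_test(g1, 1.1 * g2)
        assert x2a[0] == pytest.approx(x2b[0], rel=1e-12)


class TestMeanEwas:
    def test_null_probe_small_effect(self):
        cfg = sim.SimConfig(n_cohorts=1, n_cases=150, n_controls=150,
                            n_probes=200, seed=14)
        beta, _, _, sheet, _ = sim.generate_cohort(cfg, 0)
        res = assoc.mean_ewas(beta, sheet)
        # null: |Z| should look standard normal; mean |Z| ~ 0.8
        assert np.abs(res["z_mean"]).mean() < 1.2
        assert (res["p_mean"] < 0.001).mean() < 0.02

    def test_planted_shift_recovered_through_logistic(self):
        delta = 0.5
        cfg = sim.SimConfig(n_cohorts=1, n_cases=200, n_controls=200,
                            n_probes=40, fraction_dmp=1.0, mean_shift=delta,
                            mu_range=(0.0, 0.0), sigma_range=(0.1, 0.1001),
                            age_slope_sd=0.0, sex_offset_sd=0.0,
                            smoking_slope_sd=0.0, cell_weight_sd=0.0,
                            batch_sd=0.0, seed=15)
        beta, _, _, sheet, _ = sim.generate_cohort(cfg, 0)
        res = assoc.mean_ewas(beta, sheet)
        expected = 1 / (1 + np.exp(-delta)) - 0.5   # logistic at mu=0
        for _, row in res.iterrows():
            assert abs(row["beta"] - expected) < 4 * row["se"] + 0.01

    def test_matches_normal_equations_oracle(self, rng):
        n = 10
        sheet = pd.DataFrame({
            "diagnosis": ["case"] * 5 + ["control"] * 5,
            "horvath_age": rng.normal(45, 5, n),
        }, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, (3, n)),
                            index=sim.probe_ids(3), columns=sheet.index)
        spec = assoc.CovariateSpec(numeric=("horvath_age",), categorical=())
        res = assoc.mean_ewas(beta, sheet, spec)
        x = np.column_stack([np.ones(n),
                             (sheet["diagnosis"] == "case").astype(float),
                             sheet["horvath_age"]])
        for i in range(3):
            b_ref, se_ref = oracle_ols(x, beta.iloc[i].to_numpy())
            assert res["beta"].iloc[i] == pytest.approx(b_ref[1], rel=1e-10)
            assert res["se"].iloc[i] == pytest.approx(se_ref[1], rel=1e-10)


class TestRunCohortAssociation:
    def test_minimal_two_per_group(self, rng):
        sheet = pd.DataFrame({
            "diagnosis": ["case", "case", "control", "control"],
        }, index=pd.Index([f"s{i}" for i in range(4)], name="sample_id"))
        beta = pd.DataFrame(rng.uniform(0.3, 0.7, (5, 4)),
                            index=sim.probe_ids(5), columns=sheet.index)
        spec = assoc.CovariateSpec(numeric=(), categorical=())
        out = assoc.run_cohort_association(beta, sheet, spec)
        assert len(out) == 5
        assert (out["n_case"] == 2).all()

    def test_signed_z_p_consistency(self, small_cohort):
        out = assoc.run_cohort_association(small_cohort["beta"],
                                           small_cohort["samplesheet"])
        for name in ("levene", "bartlett", "fligner_killeen"):
            ok = out[f"z_{name}"].notna()
            z = out.loc[ok, f"z_{name}"].to_numpy()
            p = out.loc[ok, f"p_{name}"].to_numpy()
            np.testing.assert_allclose(np.abs(z), stats.norm.isf(p / 2),
                                       rtol=1e-9)

    def test_na_fraction_matches_planted_degenerates(self, rng):
        sheet = pd.DataFrame({
            "diagnosis": ["case"] * 10 + ["control"] * 10,
        }, index=pd.Index([f"s{i}" for i in range(20)], name="sample_id"))
        beta = pd.DataFrame(rng.uniform(0.3, 0.7, (30, 20)),
                            index=sim.probe_ids(30), columns=sheet.index)
        beta.iloc[:4] = 0.5     # constant probes -> degenerate dispersion
        spec = assoc.CovariateSpec(numeric=(), categorical=())
        out = assoc.run_cohort_association(beta, sheet, spec)
        assert (out["na_reason"] == "degenerate_dispersion").sum() == 4

    def test_unknown_test_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown"):
            assoc.run_cohort_association(small_cohort["beta"],
                                         small_cohort["samplesheet"],
                                         tests=("anova",))

    def test_bartlett_inflates_under_heavy_tails_fk_does_not(self, rng):
        # robustness ordering: with equal-variance t(3) noise Bartlett
        # over-rejects while the rank-based test stays near nominal
        case = rng.standard_t(3, size=(2000, 100))
        ctrl = rng.standard_t(3, size=(2000, 100))
        _, p_bart, _ = assoc.bartlett_test(case, ctrl)
        _, p_fk, _ = assoc.fligner_killeen_test(case, ctrl)
        rate_bart = (p_bart < 0.05).mean()
        rate_fk = (p_fk < 0.05).mean()
        assert rate_bart > 0.10
        assert rate_fk < 0.07

    def test_variance_sign_convention(self):
        # planted variance-up probes should skew positive in cases
        cfg = sim.SimConfig(n_cohorts=1, n_cases=150, n_controls=150,
                            n_probes=100, fraction_vmp_up=0.5,
                            variance_ratio=4.0, seed=16)
        beta, _, _, sheet, truth = sim.generate_cohort(cfg, 0)
        out = assoc.run_cohort_association(beta, sheet)
        up = truth["effect_class"] == sim.EFFECT_VAR_UP
        assert out.loc[up, "z_levene"].mean() > 1.0
        assert abs(out.loc[~up, "z_levene"].mean()) < 0.5
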