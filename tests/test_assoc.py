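import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sleepatlas.assoc import (DesignInfo, acat_combine, bh_adjust,
                              build_design_matrix, ci_containment_check,
                              encode_circular, fit_weighted_lm,
                              phenotype_effect_correlation, pool_rubin, scan,
                              wald_joint, weighted_summary, biomarker_r2)
from sleepatlas.preprocess import ImputedStack, preprocess
from sleepatlas.synthdata import SyntheticConfig, simulate


def brute_force_bh(p):
    """Independent step-up oracle: smallest slope bound, computed directly."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestEncodeCircular:
    @pytest.mark.parametrize("minutes,expected", [
        (0.0, (0.0, 1.0)),        # midnight is the angular origin
        (360.0, (1.0, 0.0)),      # 6am -> theta = pi/2
        (720.0, (0.0, -1.0)),     # noon
        (1080.0, (-1.0, 0.0)),    # 6pm -> theta = 3pi/2
    ])
    def test_reference_times(self, minutes, expected):
        s, c = encode_circular(minutes)
        np.testing.assert_allclose([s, c], expected, atol=1e-12)

    def test_unit_circle(self):
        t = np.linspace(0, 1439.9, 57)
        s, c = encode_circular(t)
        np.testing.assert_allclose(s ** 2 + c ** 2, 1.0)

    def test_out_of_range_wrapped_with_warning(self):
        with pytest.warns(UserWarning, match="wrapped"):
            s, c = encode_circular(1440.0)
        np.testing.assert_allclose([s, c], [0.0, 1.0], atol=1e-12)


class TestDesignInfo:
    def test_lonely_psu_rejected(self):
        with pytest.raises(ValueError, match="single PSU"):
            DesignInfo(strata=[0, 0, 1], psus=[0, 1, 2], weights=[1, 1, 1])

    def test_psu_in_two_strata_rejected(self):
        with pytest.raises(ValueError, match="exactly one stratum"):
            DesignInfo(strata=[0, 1, 0, 1], psus=[0, 0, 1, 1],
                       weights=[1, 1, 1, 1])

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            DesignInfo(strata=[0, 0], psus=[0, 1], weights=[1.0, 0.0])

    def test_design_df(self):
        d = DesignInfo(strata=[0] * 4 + [1] * 4,
                       psus=[0, 0, 1, 1, 2, 2, 3, 3],
                       weights=np.ones(8))
        assert d.design_df == 4 - 2


class TestFitWeightedLm:
    def test_matches_robust_ols_oracle(self, simple_design):
        """Equal weights, unit PSUs: beta = OLS, V = HC1 = HC0 * n/(n-p)."""
        rng = np.random.default_rng(0)
        n = 40
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n),
                          "z": rng.normal(size=n)})
        y = 1.0 + 0.5 * X["x"].to_numpy() + rng.normal(size=n)
        fit = fit_weighted_lm(y, X, simple_design, ["x"])
        Xm = X.to_numpy()
        beta_ols = np.linalg.lstsq(Xm, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-10)
        e = y - Xm @ beta_ols
        bread = np.linalg.inv(Xm.T @ Xm)
        hc0 = bread @ (Xm * e[:, None] ** 2).T @ Xm @ bread
        np.testing.assert_allclose(fit.cov, hc0 * n / (n - 3), rtol=1e-7)

    def test_constant_outcome(self, simple_design):
        X = pd.DataFrame({"intercept": np.ones(40),
                          "x": np.random.default_rng(1).normal(size=40)})
        fit = fit_weighted_lm(np.full(40, 3.0), X, simple_design, ["x"])
        np.testing.assert_allclose(fit.beta, [3.0, 0.0], atol=1e-12)

    def test_split_weight_duplicate_invariance(self):
        rng = np.random.default_rng(2)
        n = 30
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        design = DesignInfo(np.zeros(n, int), np.arange(n), np.ones(n))
        fit = fit_weighted_lm(y, X, design, ["x"])
        # duplicate the first observation, splitting its weight 50/50
        X2 = pd.concat([X, X.iloc[[0]]], ignore_index=True)
        y2 = np.append(y, y[0])
        w2 = np.ones(n + 1)
        w2[0] = w2[n] = 0.5
        design2 = DesignInfo(np.zeros(n + 1, int),
                             np.append(np.arange(n), 0), w2)
        fit2 = fit_weighted_lm(y2, X2, design2, ["x"])
        np.testing.assert_allclose(fit2.beta, fit.beta, rtol=1e-10)

    def test_singular_design_names_columns(self, simple_design):
        x = np.random.default_rng(3).normal(size=40)
        X = pd.DataFrame({"intercept": np.ones(40), "x": x, "x_copy": x})
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_weighted_lm(x, X, simple_design, ["x"])

    def test_stratified_variance_positive_definite(self):
        rng = np.random.default_rng(4)
        n = 120
        strata = np.repeat([0, 1, 2], 40)
        psus = strata * 4 + rng.integers(0, 4, size=n)
        design = DesignInfo(strata, psus, rng.uniform(0.5, 3.0, size=n))
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
        y = 0.2 * X["x"].to_numpy() + rng.normal(size=n)
        fit = fit_weighted_lm(y, X, design, ["x"])
        assert np.all(np.linalg.eigvalsh(fit.cov) > -1e-12)
        np.testing.assert_allclose(fit.cov, fit.cov.T)


class TestWaldJoint:
    def test_null_point(self):
        assert wald_joint(np.zeros(2), np.eye(2), design_df=50) == 1.0

    def test_chi2_limit_closed_form(self):
        # W=1, q=2, d -> inf: p = exp(-1/2)
        p = wald_joint(np.array([1.0, 0.0]), np.eye(2), design_df=10 ** 7)
        assert abs(p - np.exp(-0.5)) < 1e-4

    def test_scale_invariance(self):
        b = np.array([0.4, -0.2])
        V = np.array([[0.05, 0.01], [0.01, 0.08]])
        p1 = wald_joint(b, V, 20)
        p2 = wald_joint(3.7 * b, 3.7 ** 2 * V, 20)
        np.testing.assert_allclose(p1, p2, rtol=1e-12)

    def test_singular_cov_errors(self):
        with pytest.raises(np.linalg.LinAlgError):
            wald_joint(np.ones(2), np.ones((2, 2)), 20)

    def test_insufficient_df(self):
        with pytest.raises(ValueError, match="design df"):
            wald_joint(np.ones(3), np.eye(3), design_df=2)


class TestPoolRubin:
    def test_degenerate_identical_fits(self):
        out = pool_rubin([1.0, 1.0, 1.0], [0.04, 0.04, 0.04], complete_df=100)
        assert out.estimate == 1.0
        assert out.between_var == 0.0
        np.testing.assert_allclose(out.se, 0.2)
        assert out.df == 100

    def test_hand_computation(self):
        out = pool_rubin([1.0, 2.0, 3.0], [1.0, 1.0, 1.0], complete_df=1e9)
        assert out.estimate == 2.0
        assert out.between_var == 1.0
        np.testing.assert_allclose(out.se ** 2, 1 + (4 / 3) * 1.0)

    def test_m1_identity(self):
        out = pool_rubin([0.7], [0.01], complete_df=30)
        np.testing.assert_allclose(out.estimate, 0.7)
        np.testing.assert_allclose(out.se, 0.1)
        expected_p = 2 * stats.t.sf(0.7 / 0.1, 30)
        np.testing.assert_allclose(out.p, expected_p, rtol=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pool_rubin([], [])

    def test_barnard_rubin_df_below_complete(self):
        out = pool_rubin([0.5, 0.9, 0.1], [0.2, 0.2, 0.2], complete_df=25)
        assert 0 < out.df < 25


class TestAcat:
    def test_all_half(self):
        assert acat_combine([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_single_p_self_consistent(self):
        assert acat_combine([0.01]) == pytest.approx(0.01, rel=1e-9)

    def test_closed_form_pair(self):
        # T = tan(0.49 pi) ~ 31.8205; p returns ~0.01
        p = acat_combine([0.01, 0.01])
        assert p == pytest.approx(0.01, rel=1e-6)

    def test_tiny_p_tail_approximation(self):
        p = acat_combine([1e-20, 0.5])
        assert 0 < p < 1e-19

    def test_zero_one_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            p = acat_combine([0.0, 1.0])
        assert 0 < p < 1

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            acat_combine([0.5, 1.2])

    def test_identical_ps_passthrough(self):
        for val in (0.2, 0.7, 0.031):
            assert acat_combine([val] * 5) == pytest.approx(val, rel=1e-9)


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_all_ones(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_empty(self):
        assert bh_adjust([]).size == 0

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=1000))
    def test_matches_brute_force(self, ps):
        np.testing.assert_allclose(bh_adjust(ps), brute_force_bh(ps),
                                   rtol=1e-10, atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        assert (bh_adjust(p) >= p - 1e-12).all()


@pytest.fixture(scope="module")
def scan_setup():
    cfg = SyntheticConfig(
        n_individuals=600, n_metabolites=12, n_xenobiotic=2,
        n_phenotypes_per_domain={"Duration": 2, "Timing": 1},
        effects={("duration_1", "met_001"): 0.5},
        missing_rate_other=0.0, missing_rate_xeno=0.0, seed=31)
    cohort, phen, mat, truth = simulate(cfg)
    stack = preprocess(mat, cohort, m=3, seed=1)
    design = DesignInfo.from_cohort(cohort)
    return cohort, phen, mat, stack, design


class TestScan:
    def test_record_shape_and_fdr_family(self, scan_setup):
        cohort, phen, mat, stack, design = scan_setup
        rec = scan(stack, phen, cohort, design, model=1)
        assert len(rec) == 3 * 12
        # FDR is applied within each phenotype family
        for _, grp in rec.groupby("phenotype"):
            np.testing.assert_allclose(grp["p_fdr"],
                                       bh_adjust(grp["p"].to_numpy()))
        assert (rec["p_fdr"] >= rec["p"] - 1e-12).all()

    def test_true_effect_detected(self, scan_setup):
        cohort, phen, mat, stack, design = scan_setup
        rec = scan(stack, phen, cohort, design, model=1)
        hit = rec[(rec.phenotype == "duration_1") & (rec.metabolite == "met_001")]
        assert hit["significant"].all()

    def test_circular_records_have_no_estimate(self, scan_setup):
        cohort, phen, mat, stack, design = scan_setup
        rec = scan(stack, phen, cohort, design, model=1)
        circ = rec[rec.kind == "circular"]
        assert circ["estimate"].isna().all() and circ["p"].notna().all()

    def test_binary_recode_flips_sign_same_p(self, scan_setup):
        cohort, phen, mat, stack, design = scan_setup
        rec1 = scan(stack, phen, cohort, design, model=1)
        phen2 = type(phen)(values=phen.values.copy(), meta=phen.meta)
        binary = phen.meta.loc[phen.meta.kind == "binary", "phenotype"].iloc[0]
        phen2.values[binary] = 1.0 - phen2.values[binary]
        rec2 = scan(stack, phen2, cohort, design, model=1)
        a = rec1[rec1.phenotype == binary].set_index("metabolite")
        b = rec2[rec2.phenotype == binary].set_index("metabolite")
        np.testing.assert_allclose(a["estimate"], -b["estimate"], rtol=1e-8)
        np.testing.assert_allclose(a["p"], b["p"], rtol=1e-8)

    def test_pooling_consistency_identical_datasets(self, scan_setup):
        """With all m datasets identical, pooled output equals single-dataset."""
        cohort, phen, mat, stack, design = scan_setup
        d0 = stack.datasets[0]
        forced = ImputedStack(datasets=[d0.copy() for _ in range(3)],
                              provenance={c: "multiple" for c in d0.columns})
        single = ImputedStack(datasets=[d0.copy()],
                              provenance={c: "none" for c in d0.columns})
        rec_m = scan(forced, phen, cohort, design, model=1)
        rec_1 = scan(single, phen, cohort, design, model=1)
        np.testing.assert_allclose(rec_m["estimate"], rec_1["estimate"],
                                   rtol=1e-12)
        np.testing.assert_allclose(rec_m["p"], rec_1["p"], rtol=1e-9)

    def test_sex_stratified_drops_sex(self, scan_setup):
        cohort, phen, mat, stack, design = scan_setup
        rec = scan(stack, phen, cohort, design, model=1, stratum="female")
        assert (rec["stratum"] == "female").all()
        assert len(rec) == 3 * 12


class TestCiContainment:
    def _records(self, b1, se1, b2):
        m1 = pd.DataFrame({"phenotype": ["p"], "metabolite": ["m"],
                           "kind": ["continuous"], "estimate": [b1],
                           "se": [se1]})
        m2 = pd.DataFrame({"phenotype": ["p"], "metabolite": ["m"],
                           "estimate": [b2]})
        return m1, m2

    def test_inside_ci_not_flagged(self):
        m1, m2 = self._records(1.0, 0.5, 1.5)
        out = ci_containment_check(m1, m2, design_df=1e6)
        assert not out["outside_ci"].iloc[0]

    def test_equal_estimates_not_flagged(self):
        m1, m2 = self._records(1.0, 0.5, 1.0)
        assert not ci_containment_check(m1, m2, 1e6)["outside_ci"].iloc[0]

    def test_outside_ci_flagged(self):
        m1, m2 = self._records(0.0, 0.1, 0.5)
        assert ci_containment_check(m1, m2, 1e6)["outside_ci"].iloc[0]

    def test_circular_skipped(self):
        m1 = pd.DataFrame({"phenotype": ["t"], "metabolite": ["m"],
                           "kind": ["circular"], "estimate": [np.nan],
                           "se": [np.nan]})
        m2 = pd.DataFrame({"phenotype": ["t"], "metabolite": ["m"],
                           "estimate": [np.nan]})
        out = ci_containment_check(m1, m2, 100)
        assert out.empty


class TestWeightedSummary:
    def test_equal_weights_is_plain_mean(self, simple_design):
        x = pd.Series(np.arange(40, dtype=float))
        assert weighted_summary(x, simple_design) == pytest.approx(19.5)

    def test_hand_computation(self):
        design = DesignInfo([0, 0], [0, 1], [1.0, 3.0])
        x = pd.Series([0.0, 10.0])
        assert weighted_summary(x, design) == pytest.approx(7.5)

    def test_proportions_sum_to_one(self):
        design = DesignInfo([0] * 6, np.arange(6), [1, 2, 3, 1, 2, 3.0])
        x = pd.Series(["a", "a", "b", "c", "b", "c"])
        props = weighted_summary(x, design)
        assert sum(props.values()) == pytest.approx(1.0)

    def test_all_missing_errors(self, simple_design):
        with pytest.raises(ValueError):
            weighted_summary(pd.Series([np.nan] * 40), simple_design)


class TestBiomarkerR2:
    def test_perfect_metabolite(self, scan_setup):
        cohort, phen, mat, stack, design = scan_setup
        y = phen.values["duration_1"]
        r_met, r_cov, r_both = biomarker_r2(
            y, "continuous", y.copy(), cohort, design)
        assert r_met == pytest.approx(1.0)
        assert r_both == pytest.approx(1.0)

    def test_independent_metabolite_near_zero(self, scan_setup):
        cohort, phen, mat, stack, design = scan_setup
        rng = np.random.default_rng(0)
        met = pd.Series(rng.normal(size=len(cohort)), index=cohort.index)
        r_met, r_cov, r_both = biomarker_r2(
            phen.values["duration_1"], "continuous", met, cohort, design)
        assert abs(r_met) < 0.02
        assert r_both <= r_cov + 0.02

    def test_circular_unsupported(self, scan_setup):
        cohort, phen, mat, stack, design = scan_setup
        with pytest.raises(ValueError, match="circular"):
            biomarker_r2(phen.values["timing_1"], "circular",
                         phen.values["timing_1"], cohort, design)


class TestPhenotypeEffectCorrelation:
    def _records(self, est_a, est_b):
        rows = []
        for i, (a, b) in enumerate(zip(est_a, est_b)):
            rows.append(("pa", "continuous", f"m{i}", a))
            rows.append(("pb", "continuous", f"m{i}", b))
        return pd.DataFrame(rows, columns=["phenotype", "kind", "metabolite",
                                           "estimate"])

    def test_self_correlation_one(self):
        est = np.random.default_rng(0).normal(size=20)
        rec = self._records(est, est)
        mat = phenotype_effect_correlation(rec)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        assert mat.loc["pa", "pb"] == pytest.approx(1.0)

    def test_identical_rank_order_of_squares(self):
        a = np.array([0.1, -0.2, 0.3, -0.4, 0.5])
        b = 2 * a  # same rank order of squared effects
        mat = phenotype_effect_correlation(self._records(a, b))
        assert mat.loc["pa", "pb"] == pytest.approx(1.0)

    def test_independent_effects_near_zero(self):
        rng = np.random.default_rng(1)
        vals = [phenotype_effect_correlation(
            self._records(rng.normal(size=768), rng.normal(size=768))
        ).loc["pa", "pb"] for _ in range(20)]
        assert np.mean(np.abs(vals)) < 0.1

    def test_too_few_shared_metabolites_nan(self):
        rec = self._records([0.1, 0.2], [0.3, 0.4])
        mat = phenotype_effect_correlation(rec, min_shared=3)
        assert np.isnan(mat.loc["pa", "pb"])
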