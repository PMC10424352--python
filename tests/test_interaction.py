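import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amdgxe import (
    SimulationConfig,
    additive_measures,
    bootstrap_cis,
    delta_cis,
    fit_interaction_model,
    joint_odds_ratios,
    multiplicative_measure,
    recode_protective,
    simulate_eye_records,
    stratified_ors,
    stratified_ors_refit,
)
from amdgxe.gee import GeeError, GeeFit
from amdgxe.interaction import ap_gradient, log_si_gradient, reri_gradient


def _fake_fit(bg, bd, bgd, cov=None):
    names = ["intercept", "high_grs", "low_mediscore", "grs_x_diet"]
    params = pd.Series([0.0, bg, bd, bgd], index=names)
    if cov is None:
        cov = np.zeros((4, 4))
    return GeeFit(
        params=params, cov=pd.DataFrame(cov, index=names, columns=names),
        alpha=0.0, scale=1.0, n_clusters=10, n_records=20, converged=True, n_iter=2,
    )


class TestRecode:
    def test_first_call_yields_risk_coding(self):
        rec = pd.DataFrame({"high_mediscore": [True, False]})
        out = recode_protective(rec)
        assert out.attrs["diet_coding"] == "risk"
        assert list(out["diet_exposure"]) == [0, 1]  # exposure = low adherence

    def test_recode_twice_is_involution(self):
        rec = pd.DataFrame({"high_mediscore": [True, False, True]})
        once = recode_protective(rec)
        twice = recode_protective(once)
        assert twice.attrs["diet_coding"] == "protective"
        assert list(twice["diet_exposure"]) == [1, 0, 1]


class TestJointOrs:
    def test_no_interaction_product_structure(self):
        j = joint_odds_ratios(_fake_fit(np.log(2.0), np.log(3.0), 0.0))
        assert j.loc["or01", "or"] == pytest.approx(2.0)
        assert j.loc["or10", "or"] == pytest.approx(3.0)
        assert j.loc["or11", "or"] == pytest.approx(6.0)

    def test_null_coefficients_give_unit_ors(self):
        j = joint_odds_ratios(_fake_fit(0.0, 0.0, 0.0))
        assert np.allclose(j["or"], 1.0)

    def test_published_scale_example(self):
        j = joint_odds_ratios(_fake_fit(0.581, 0.845, 0.105))
        assert j.loc["or11", "or"] == pytest.approx(np.exp(1.531), rel=1e-12)
        assert j.loc["or11", "or"] == pytest.approx(4.623, abs=5e-4)

    def test_missing_interaction_term_rejected(self):
        fit = _fake_fit(0.1, 0.2, 0.3)
        fit.params = fit.params.drop("grs_x_diet")
        with pytest.raises(GeeError, match="grs_x_diet"):
            joint_odds_ratios(fit)


class TestMultiplicative:
    def test_equals_or_ratio_identity_on_real_fit(self, eye_records_small):
        fit = fit_interaction_model(eye_records_small)
        j = joint_odds_ratios(fit)
        m = multiplicative_measure(fit)
        ratio = j.loc["or11", "or"] / (j.loc["or01", "or"] * j.loc["or10", "or"])
        assert m["or"] == pytest.approx(ratio, rel=1e-12)
        assert m["or"] == pytest.approx(np.exp(fit.params["grs_x_diet"]), rel=1e-12)

    def test_null_and_doubling_cases(self):
        assert multiplicative_measure(_fake_fit(0.5, 0.7, 0.0))["or"] == pytest.approx(1.0)
        assert multiplicative_measure(_fake_fit(0.5, 0.7, np.log(2.0)))["or"] == pytest.approx(2.0)


class TestAdditiveMeasures:
    def test_plugin_of_additivity_identity(self):
        m = additive_measures(3.0, 2.0, 2.0)  # or11 = or01 + or10 - 1
        assert m["reri"] == pytest.approx(0.0)
        assert m["ap"] == pytest.approx(0.0)
        assert m["si"] == pytest.approx(1.0)

    @settings(max_examples=80, deadline=None)
    @given(
        or01=st.floats(min_value=1.05, max_value=6.0),
        or10=st.floats(min_value=1.05, max_value=6.0),
    )
    def test_pure_additivity_null_holds_for_any_ors(self, or01, or10):
        m = additive_measures(or01 + or10 - 1.0, or01, or10)
        assert abs(m["reri"]) < 1e-12
        assert abs(m["ap"]) < 1e-12
        assert m["si"] == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        ors=st.tuples(*[st.floats(min_value=0.2, max_value=10.0)] * 3),
    )
    def test_formula_identities_and_sign_coupling(self, ors):
        or11, or01, or10 = ors
        m = additive_measures(or11, or01, or10)
        assert m["reri"] == pytest.approx(or11 - or01 - or10 + 1.0)
        assert m["ap"] == pytest.approx(m["reri"] / or11)
        assert np.sign(m["ap"]) == np.sign(m["reri"])  # since or11 > 0

    def test_si_denominator_zero_flagged(self):
        m = additive_measures(2.0, 1.5, 0.5)  # (or01-1)+(or10-1) = 0
        assert not m["si_defined"] and np.isnan(m["si"])

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            additive_measures(0.0, 1.0, 1.0)


class TestDeltaMethod:
    @pytest.mark.parametrize(
        "analytic, fn",
        [
            (reri_gradient, lambda b: np.exp(b.sum()) - np.exp(b[0]) - np.exp(b[1]) + 1.0),
            (ap_gradient, lambda b: (np.exp(b.sum()) - np.exp(b[0]) - np.exp(b[1]) + 1.0) / np.exp(b.sum())),
            (log_si_gradient, lambda b: np.log((np.exp(b.sum()) - 1.0) / (np.exp(b[0]) + np.exp(b[1]) - 2.0))),
        ],
    )
    def test_gradients_match_finite_differences(self, analytic, fn):
        rng = np.random.default_rng(7)
        for _ in range(5):
            b = rng.uniform(0.3, 1.2, 3)  # region where all three are defined
            grad = analytic(*b)
            eps = 1e-7
            for k in range(3):
                bp, bm = b.copy(), b.copy()
                bp[k] += eps
                bm[k] -= eps
                numeric = (fn(bp) - fn(bm)) / (2 * eps)
                assert grad[k] == pytest.approx(numeric, abs=1e-6)

    def test_zero_covariance_gives_zero_width_intervals(self):
        table = delta_cis(_fake_fit(0.6, 0.8, 0.2))
        for name in ("reri", "ap"):
            row = table.loc[name]
            assert row["ci_low"] == pytest.approx(row["estimate"])
            assert row["ci_high"] == pytest.approx(row["estimate"])
        si = table.loc["si"]
        assert si["ci_low"] == pytest.approx(si["estimate"])

    def test_non_psd_covariance_rejected(self):
        bad = np.diag([0.0, -1.0, 0.1, 0.1])
        with pytest.raises(GeeError, match="positive semidefinite"):
            delta_cis(_fake_fit(0.5, 0.5, 0.1, cov=bad))


class TestBootstrap:
    def test_same_seed_reproduces_cis(self, eye_records_small):
        a = bootstrap_cis(eye_records_small, n_boot=20, seed=5)
        b = bootstrap_cis(eye_records_small, n_boot=20, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_two_replicate_smoke_case(self, eye_records_small):
        out = bootstrap_cis(eye_records_small, n_boot=2, seed=1)
        assert set(out.index) == {"reri", "ap", "si"}
        assert (out["n_replicates"] <= 2).all()

    def test_too_few_replicates_rejected(self, eye_records_small):
        with pytest.raises(ValueError):
            bootstrap_cis(eye_records_small, n_boot=1, seed=1)


class TestStratified:
    def test_reciprocal_protective_direction(self):
        strat = stratified_ors(_fake_fit(0.581, 0.845, 0.105))
        risk_or = strat.loc["diet_high_grs", "or"]
        assert strat.loc["diet_high_grs", "or_protective"] == pytest.approx(1.0 / risk_or)

    def test_no_interaction_equalizes_strata(self):
        strat = stratified_ors(_fake_fit(0.6, 0.9, 0.0))
        assert strat.loc["diet_low_grs", "or"] == pytest.approx(strat.loc["diet_high_grs", "or"])
        assert strat.loc["grs_low_diet", "or"] == pytest.approx(strat.loc["grs_high_diet", "or"])

    def test_refit_route_concordant_with_linear_combination(self):
        records = simulate_eye_records(SimulationConfig(n_subjects=4000, seed=21))
        fit = fit_interaction_model(records)
        combo = stratified_ors(fit)
        refit = stratified_ors_refit(records)
        for key in ("diet_low_grs", "diet_high_grs"):
            a, b = combo.loc[key, "or"], refit.loc[key, "or"]
            assert np.sign(np.log(a)) == np.sign(np.log(b))
            assert a == pytest.approx(b, rel=0.25)


class TestScaleSeparation:
    def test_multiplicative_null_coexists_with_nonzero_reri(self):
        # under a generating model with no product term, exp(b_GD) centres
        # at 1 while RERI stays positive: the two scales measure different
        # things
        mult, reri = [], []
        for rep in range(30):
            cfg = SimulationConfig(n_subjects=2500, seed=3000 + rep, beta_interaction=0.0)
            fit = fit_interaction_model(simulate_eye_records(cfg))
            mult.append(multiplicative_measure(fit)["or"])
            j = joint_odds_ratios(fit)
            reri.append(additive_measures(j.loc["or11", "or"], j.loc["or01", "or"],
                                          j.loc["or10", "or"])["reri"])
        mult, reri = np.array(mult), np.array(reri)
        assert abs(np.log(mult).mean()) < 3 * np.log(mult).std(ddof=1) / np.sqrt(len(mult))
        assert reri.mean() > 3 * reri.std(ddof=1) / np.sqrt(len(reri))
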