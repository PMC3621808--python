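import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from sportmed.multilevel import (
    MixedModelFit,
    SingularDesignError,
    ThreeLevelLinearRegression,
    ThreeLevelLogisticRegression,
    fit_three_level,
    wald_test,
)

OUTCOME_FIXED = ["financial", "attitude", "belief", "enjoyment", "pbc", "sex", "age_years"]

# Reference fits computed once on tests/data/fixture_cohort.csv with
# lme4 1.1-37 (glmer Laplace / lmer ML) and frozen here.
LME4_LOGIT_COEF = {
    "Intercept": 1.9106631661,
    "financial": 0.0400302511,
    "attitude": 0.4156968040,
    "belief": 0.1661032339,
    "enjoyment": 0.5022912260,
    "pbc": 0.6221732292,
    "sex": 0.6584064206,
    "age_years": -0.1438658725,
}
LME4_LOGIT_LL = -230.607967
LME4_LMM_COEF = {
    "Intercept": 0.0699970334567,
    "financial": 0.2207686635280,
    "sex": 0.0007829353035,
    "age_years": -0.0560816852696,
}
LME4_LMM_VC = {"school": 0.034319287, "country": 0.028239344, "residual": 1.004725344}
LME4_LMM_LL = -605.357446


def _sim_flat_logit(n=2000, seed=42):
    """Binary data with no group structure at all (zero variance components)."""
    rng = np.random.default_rng(seed)
    x1, x2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
    eta = -0.3 + 0.8 * x1 - 0.5 * x2
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    groups = np.column_stack(
        [rng.integers(0, 7, n).astype(str), rng.integers(0, 5, n).astype(str)]
    )
    return pd.DataFrame({"x1": x1, "x2": x2}), y, groups


class TestLogisticFit:
    def test_degenerates_to_single_level_logistic(self):
        X, y, groups = _sim_flat_logit()
        fit = ThreeLevelLogisticRegression().fit(X, y, groups).result_
        glm = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.abs(fit.params.to_numpy() - glm.params.to_numpy()).max() < 1e-3
        assert np.abs(fit.se.to_numpy() - glm.bse.to_numpy()).max() < 1e-3
        assert fit.vc["country"] < 1e-4 and fit.vc["school"] < 1e-4

    def test_matches_reference_implementation_on_fixture(self, fixture_cohort):
        fit = fit_three_level(fixture_cohort, "sport_participant", OUTCOME_FIXED, link="logit")
        ref = np.array([LME4_LOGIT_COEF[k] for k in fit.params.index])
        rel = np.abs(fit.params.to_numpy() - ref) / np.abs(ref)
        assert rel.max() < 1e-2
        assert fit.loglik >= LME4_LOGIT_LL - 0.01  # at least as good an optimum
        assert fit.converged

    def test_agq_agrees_with_laplace(self, fixture_cohort):
        lap = fit_three_level(fixture_cohort, "sport_participant", OUTCOME_FIXED, link="logit")
        agq = fit_three_level(
            fixture_cohort, "sport_participant", OUTCOME_FIXED, link="logit",
            method="agq", n_quad=7,
        )
        rel = np.abs(agq.params.to_numpy() - lap.params.to_numpy()) / np.maximum(
            np.abs(lap.params.to_numpy()), 0.05
        )
        assert rel.max() < 0.02
        assert agq.loglik >= lap.loglik - 0.5

    def test_row_permutation_invariance(self, fixture_cohort):
        base = fit_three_level(fixture_cohort, "sport_participant", OUTCOME_FIXED, link="logit")
        shuffled = fixture_cohort.sample(frac=1.0, random_state=5).reset_index(drop=True)
        perm = fit_three_level(shuffled, "sport_participant", OUTCOME_FIXED, link="logit")
        assert np.abs(base.params.to_numpy() - perm.params.to_numpy()).max() < 1e-5

    def test_covariate_shift_moves_only_intercept(self, fixture_cohort):
        base = fit_three_level(
            fixture_cohort, "sport_participant", ["pbc", "sex"], link="logit"
        )
        shifted = fixture_cohort.copy()
        shifted["pbc"] = shifted["pbc"] + 10.0
        moved = fit_three_level(shifted, "sport_participant", ["pbc", "sex"], link="logit")
        assert abs(moved.params["pbc"] - base.params["pbc"]) < 1e-4
        assert abs(moved.params["sex"] - base.params["sex"]) < 1e-4
        assert abs(
            (moved.params["Intercept"] + 10 * moved.params["pbc"]) - base.params["Intercept"]
        ) < 1e-3

    def test_or_view_is_exp_of_coefficients(self, fixture_cohort):
        fit = fit_three_level(fixture_cohort, "sport_participant", ["pbc"], link="logit")
        view = fit.odds_ratios()
        assert np.allclose(view["OR"], np.exp(fit.params))
        assert np.allclose(view["ci_low"], np.exp(fit.params - 1.959964 * fit.se))

    def test_collinear_design_named(self, fixture_cohort):
        df = fixture_cohort.copy()
        df["pbc_twice"] = 2 * df["pbc"]
        with pytest.raises(SingularDesignError, match="pbc"):
            fit_three_level(df, "sport_participant", ["pbc", "pbc_twice"], link="logit")

    def test_non_binary_outcome_rejected(self, fixture_cohort):
        with pytest.raises(ValueError, match="binary"):
            fit_three_level(fixture_cohort, "pbc", ["financial"], link="logit")


class TestLinearFit:
    def test_matches_reference_implementation_on_fixture(self, fixture_cohort):
        fit = fit_three_level(
            fixture_cohort, "pbc", ["financial", "sex", "age_years"], link="identity"
        )
        ref = np.array([LME4_LMM_COEF[k] for k in fit.params.index])
        assert np.abs(fit.params.to_numpy() - ref).max() < 1e-3
        for level, v in LME4_LMM_VC.items():
            assert abs(fit.vc[level] - v) < 1e-2
        assert abs(fit.loglik - LME4_LMM_LL) < 1e-2

    def test_recovers_generative_fixed_effect(self, recovery_cohort):
        fit = fit_three_level(recovery_cohort, "pbc", ["financial", "sex"], link="identity")
        # generative a-path 0.18, slight attenuation from grid rounding
        assert abs(fit.params["financial"] - 0.18) < 0.035

    def test_variance_components_nonnegative(self, fixture_cohort):
        fit = fit_three_level(fixture_cohort, "enjoyment", ["financial"], link="identity")
        assert fit.vc["country"] >= 0 and fit.vc["school"] >= 0


class TestWald:
    @pytest.mark.parametrize(
        "coef, se, z, ci",
        [
            (0.0, 1.0, 0.0, (-1.959964, 1.959964)),
            (0.5, 0.1, 5.0, (0.3040036, 0.6959964)),
            (-0.2, 0.1, -2.0, (-0.3959964, -0.0040036)),
        ],
    )
    def test_closed_form(self, coef, se, z, ci):
        fit = _trivial_fit({"x": coef}, {"x": se})
        w = wald_test(fit, "x")
        assert w.z == pytest.approx(z)
        assert w.ci == pytest.approx(ci)
        if coef == 0:
            assert w.p == pytest.approx(1.0)
        if coef == -0.2:
            assert w.ci[1] < 0  # excludes zero

    def test_zero_se_undefined(self):
        with pytest.raises(ZeroDivisionError):
            wald_test(_trivial_fit({"x": 1.0}, {"x": 0.0}), "x")


def _trivial_fit(params: dict, ses: dict) -> MixedModelFit:
    names = list(params)
    cov = np.diag([ses[k] ** 2 for k in names])
    return MixedModelFit(
        params=pd.Series(params),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        vc={"country": 0.0, "school": 0.0},
        n_obs=0,
        loglik=0.0,
        converged=True,
        link="logit",
        n_groups={"country": 0, "school": 0},
    )


class TestSerialization:
    def test_json_round_trip(self, fixture_cohort):
        fit = fit_three_level(fixture_cohort, "pbc", ["financial"], link="identity")
        back = MixedModelFit.from_json(fit.to_json())
        assert np.allclose(back.params, fit.params)
        assert np.allclose(back.cov_params, fit.cov_params)
        assert back.vc == fit.vc and back.link == fit.link
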