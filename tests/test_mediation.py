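import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sportmed import reference, simulate
from sportmed.mediation import (
    MultilevelMediation,
    SingleMediationResult,
    classify_mediation,
    estimate_paths,
    percent_mediated,
    select_mediators,
    sobel,
    total_mediated,
)


class TestSobel:
    def test_zero_a_collapses_to_b_times_se_a(self):
        effect, se, _ = sobel(0.0, 0.1, 0.7, 0.05)
        assert effect == 0.0 and se == pytest.approx(0.07)

    def test_hand_evaluated_case(self):
        effect, se, ci = sobel(0.5, 0.1, 0.3, 0.05)
        assert effect == pytest.approx(0.15)
        assert se == pytest.approx(np.sqrt(0.25 * 0.0025 + 0.09 * 0.01))  # 0.039051
        assert ci[0] == pytest.approx(0.15 - 1.959964 * se)

    @given(
        a=st.floats(-2, 2), b=st.floats(-2, 2),
        se_a=st.floats(0, 0.5), se_b=st.floats(0, 0.5),
    )
    @settings(derandomize=True, max_examples=60)
    def test_symmetric_in_paths(self, a, b, se_a, se_b):
        assert sobel(a, se_a, b, se_b)[1] == pytest.approx(sobel(b, se_b, a, se_a)[1])

    def test_degenerate_ses_allowed(self):
        assert sobel(0.5, 0.0, 0.3, 0.0)[1] == 0.0


class TestTotalMediated:
    def test_single_mediator_reduces_to_sobel(self):
        effects, total, se, ci = total_mediated([0.4], [0.1], [0.5], [[0.04]])
        s_eff, s_se, s_ci = sobel(0.4, 0.1, 0.5, 0.2)
        assert total == pytest.approx(s_eff) and se == pytest.approx(s_se)
        assert ci == pytest.approx(s_ci)

    def test_hand_evaluated_two_mediators(self):
        effects, total, se, _ = total_mediated(
            [0.3, 0.2], [0.05, 0.05], [0.4, 0.6], [[0.01, 0.002], [0.002, 0.01]]
        )
        assert total == pytest.approx(0.24)
        # 0.3^2*0.01 + 0.4^2*0.0025 + 0.2^2*0.01 + 0.6^2*0.0025 + 2*0.3*0.2*0.002
        assert se**2 == pytest.approx(0.00284)

    def test_total_is_exact_sum_of_parts(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=4), rng.normal(size=4)
        effects, total, _, _ = total_mediated(a, np.full(4, 0.1), b, np.eye(4) * 0.01)
        assert total == effects.sum()  # machine precision identity

    def test_positive_b_covariance_inflates_se(self):
        _, _, se_indep, _ = total_mediated([0.3, 0.2], [0.05, 0.05], [0.4, 0.6],
                                           np.diag([0.01, 0.01]))
        _, _, se_corr, _ = total_mediated([0.3, 0.2], [0.05, 0.05], [0.4, 0.6],
                                          [[0.01, 0.004], [0.004, 0.01]])
        assert se_corr > se_indep

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            total_mediated([0.1, 0.2], [0.1], [0.3, 0.4], np.eye(2))

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError, match="negative|PSD"):
            total_mediated([1.0], [0.0], [1.0], [[-0.5]])

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_delta_se_matches_parametric_monte_carlo(self, case_seed):
        """Independent oracle: SD of sum(a_i* b_i*) over parametric draws.

        Admissible inputs keep every relative SE below 25%, the regime in
        which the first-order delta method is quoted.
        """
        rng = np.random.default_rng(case_seed)
        k = int(rng.integers(1, 5))
        a = rng.uniform(0.2, 1.5, k) * rng.choice([-1, 1], k)
        b = rng.uniform(0.2, 1.5, k) * rng.choice([-1, 1], k)
        se_a = np.abs(a) * rng.uniform(0.02, 0.25, k)
        sd_b = np.abs(b) * rng.uniform(0.02, 0.25, k)
        corr = rng.uniform(-0.9 / max(k - 1, 1), 0.8)  # keeps the matrix PSD
        C = np.full((k, k), corr) + (1 - corr) * np.eye(k)
        C = C * np.outer(sd_b, sd_b)
        _, _, se_delta, _ = total_mediated(a, se_a, b, C)

        n_draws = 60_000
        a_star = rng.normal(a, se_a, size=(n_draws, k))
        b_star = rng.multivariate_normal(b, C, size=n_draws)
        mc_sd = (a_star * b_star).sum(axis=1).std(ddof=1)
        assert se_delta == pytest.approx(mc_sd, rel=0.03)


class TestParametricDraws:
    def test_draw_sd_approaches_delta_se(self):
        from sportmed.mediation import parametric_total_draws

        a, se_a = [0.5, 0.4], [0.04, 0.05]
        b, C = [0.6, 0.3], np.diag([0.002, 0.003])
        _, total, se_delta, _ = total_mediated(a, se_a, b, C)
        draws = parametric_total_draws(a, se_a, b, C, n_draws=80_000, rng=0)
        assert draws.mean() == pytest.approx(total, abs=4 * se_delta / np.sqrt(80_000) + 1e-3)
        assert draws.std(ddof=1) == pytest.approx(se_delta, rel=0.03)


class TestPercentMediated:
    def test_zero_direct_effect_gives_full_percentage(self):
        per, total_pct, flag = percent_mediated([0.05], 0.05, 0.0)
        assert total_pct == pytest.approx(100.0)

    def test_published_parts_sum_to_total_percentage(self):
        # equipment block of the published multiple-mediator model
        effects = [0.008, 0.003, 0.016, 0.029]
        total = sum(effects)
        c_prime = np.log(reference.TOTAL_DIRECT["equipment"].direct_or)
        per, total_pct, flag = percent_mediated(effects, total, c_prime)
        assert per.sum() == pytest.approx(total_pct)
        assert not flag

    def test_hand_evaluated_ratio(self):
        _, total_pct, _ = percent_mediated([0.03], 0.03, 0.10)
        assert total_pct == pytest.approx(100 * 0.03 / 0.13)  # 23.08%

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            percent_mediated([0.1], 0.1, -0.1)

    def test_sign_conflict_flagged_unreliable(self):
        _, _, flag = percent_mediated([-0.05], -0.05, 0.2)
        assert flag


def _single(mediator, effect, lo, hi):
    se = (hi - lo) / (2 * 1.959964)
    return SingleMediationResult("x", mediator, 1.0, 0.0, effect, se, effect, se, (lo, hi))


class TestSelection:
    def test_published_reinforcement_pattern(self):
        singles = [
            _single(m, r.mediated, *r.mediated_ci)
            for m, r in reference.SINGLE_MODELS["reinforcement"].items()
        ]
        assert select_mediators(singles) == ["enjoyment", "pbc"]

    def test_all_or_none(self):
        strong = [_single(m, 0.1, 0.05, 0.15) for m in "abcd"]
        assert select_mediators(strong) == list("abcd")
        weak = [_single(m, 0.01, -0.05, 0.07) for m in "abcd"]
        assert select_mediators(weak) == []

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_mediators([])


class TestClassification:
    @pytest.mark.parametrize(
        "c, cp, total, tot_sig, cp_sig, label",
        [
            (0.0, -0.01, 0.03, True, False, "inconsistent"),  # suppression
            (0.4, 0.3, 0.1, True, True, "partial"),
            (0.2, 0.05, 0.15, True, False, "full"),
            (0.2, 0.15, 0.05, False, True, "none"),
        ],
    )
    def test_patterns(self, c, cp, total, tot_sig, cp_sig, label):
        assert classify_mediation(c, cp, total, tot_sig, cp_sig) == label


@pytest.fixture(scope="module")
def no_b_cohort():
    t = simulate.recovery_truth(seed=21, schools_per_country=8, children_per_school=40)
    t.b_vector = {m: 0.0 for m in t.mediator_names}
    return simulate.generate_cohort(t), t


class TestEstimatePaths:

    def test_b_zero_makes_c_equal_c_prime(self, no_b_cohort):
        df, t = no_b_cohort
        paths = estimate_paths(df, "financial")
        assert np.abs(paths.b.to_numpy()).max() < 0.15  # all b near zero
        assert abs(paths.c - paths.c_prime) < 0.05

    def test_single_mediator_cov_block_is_se_squared(self, no_b_cohort):
        df, _ = no_b_cohort
        paths = estimate_paths(df, "financial", mediators=["pbc"])
        assert paths.cov_b.shape == (1, 1)
        se_b = float(np.sqrt(paths.cov_b.iloc[0, 0]))
        assert se_b == pytest.approx(float(paths.joint_fit.se["pbc"]))

    def test_recovers_generative_paths(self, recovery_cohort):
        t = simulate.recovery_truth(seed=3)
        paths = estimate_paths(recovery_cohort, "financial")
        for m in ("enjoyment", "pbc"):  # the two largest generative paths
            assert paths.a[m] == pytest.approx(t.a_matrix[m]["financial"], abs=0.04)
            assert paths.b[m] == pytest.approx(t.b_vector[m], abs=0.20)


class TestMultilevelMediationEstimator:
    def test_sklearn_param_protocol(self):
        est = MultilevelMediation(alpha=0.1)
        assert est.get_params()["alpha"] == 0.1
        est.set_params(alpha=0.05, exposures=("financial",))
        assert est.get_params()["exposures"] == ("financial",)

    def test_overlapping_roles_rejected(self, recovery_cohort):
        with pytest.raises(ValueError, match="overlap"):
            MultilevelMediation(exposures=("pbc",)).fit(recovery_cohort)

    def test_missing_values_rejected(self, recovery_cohort):
        df = recovery_cohort.copy()
        df.loc[0, "pbc"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            MultilevelMediation(exposures=("financial",)).fit(df)

    def test_full_fit_consistency(self, recovery_cohort):
        est = MultilevelMediation(exposures=("financial",)).fit(recovery_cohort)
        res = est.multiple_["financial"]
        assert res is not None
        # total = sum of parts, machine precision
        assert res.total == pytest.approx(sum(res.effects.values()), abs=1e-15)
        # percentages sum to the total percentage when reported
        if res.percent is not None:
            assert sum(res.percent.values()) == pytest.approx(res.percent_total)
        # delta SE is at least each mediator's own Sobel contribution
        paths = est.paths_["financial"]
        for i, m in enumerate(res.mediators):
            _, se_i, _ = sobel(
                paths.a.iloc[i], paths.se_a.iloc[i],
                paths.b.iloc[i], float(np.sqrt(paths.cov_b.iloc[i, i])),
            )
            assert res.se_total >= se_i - 1e-12
        # CI covers the generative truth in this realization
        truth_total = sum(
            simulate.true_mediated_effects(simulate.recovery_truth(seed=3), "financial").values()
        )
        lo, hi = res.ci_total
        assert lo < truth_total < hi
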