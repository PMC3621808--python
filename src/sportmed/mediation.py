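"""Product-of-coefficients mediation for three-level binary-outcome models.

For one family-environment exposure X, mediators M_i and the binary sport
outcome Y, the engine fits (all as three-level random-intercept models,
adjusted for sex, age and parental education):

* c-path:   logit Y ~ X                     (total effect, log-odds)
* a-paths:  M_i ~ X                         (one linear model per mediator)
* b-paths:  logit Y ~ M_i + X               (single-mediator models), and
            logit Y ~ M_1..M_k + X          (one joint multiple-mediator
            model, whose X coefficient is the direct effect c')

The indirect effect of mediator i is a_i * b_i.  Its standard error in a
single-mediator model is Sobel's first-order formula
``sqrt(a^2 SE_b^2 + b^2 SE_a^2)``.  In the multiple-mediator model the
total indirect effect is ``sum_i a_i b_i`` with the multivariate
delta-method variance

    sum_i (a_i^2 Var(b_i) + b_i^2 Var(a_i))
        + sum_{i != j} a_i a_j Cov(b_i, b_j),

where the b-covariances come from the joint outcome fit; the a-paths are
estimated in separate models and treated as independent (an a-covariance
can be supplied when available).  Percent mediated divides indirect
effects by (c' + total indirect); it is suppressed when mediation is
inconsistent (direct and indirect effects of opposite sign), where the
decomposition has no interpretation.

All effects stay on the log-odds scale throughout; odds ratios are a
reporting-layer view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .multilevel import Z95, MixedModelFit, fit_three_level, wald_test

__all__ = [
    "sobel",
    "total_mediated",
    "percent_mediated",
    "select_mediators",
    "classify_mediation",
    "estimate_paths",
    "PathEstimates",
    "SingleMediationResult",
    "MultipleMediationResult",
    "MultilevelMediation",
    "expand_covariates",
    "parametric_total_draws",
]

log = logging.getLogger(__name__)

DEFAULT_EXPOSURES = (
    "equipment",
    "financial",
    "logistic",
    "emotional",
    "reinforcement",
    "modelling",
    "coparticipation",
)
DEFAULT_MEDIATORS = ("attitude", "belief", "enjoyment", "pbc")
DEFAULT_COVARIATES = ("sex", "age_years", "parent_education")

EDU_DUMMIES = ("edu_12_13", "edu_ge14")


class UndefinedPercentageError(ZeroDivisionError):
    """c' + total mediated effect is zero; percent mediated is undefined."""


# ---------------------------------------------------------------------------
# pure computations


def sobel(a: float, se_a: float, b: float, se_b: float):
    """Indirect effect a*b with Sobel's first-order SE and 95% CI."""
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be non-negative")
    effect = a * b
    se = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))
    return effect, se, (effect - Z95 * se, effect + Z95 * se)


def total_mediated(a_vec, se_a_vec, b_vec, cov_b, a_cov=None):
    """Summed indirect effect with the multivariate delta-method SE.

    Parameters are aligned vectors of a-path estimates and SEs, b-path
    estimates, and the b-block covariance matrix from the joint outcome
    model.  ``a_cov`` optionally supplies a full a-covariance matrix; by
    default the a's are independent (separate models).

    Returns ``(per_mediator_effects, total, se_total, ci_total)``.
    """
    a = np.asarray(a_vec, dtype=float)
    se_a = np.asarray(se_a_vec, dtype=float)
    b = np.asarray(b_vec, dtype=float)
    C = np.asarray(cov_b, dtype=float)
    if C.ndim == 0:
        C = C.reshape(1, 1)
    k = len(a)
    if not (len(se_a) == len(b) == C.shape[0] == C.shape[1] == k):
        raise ValueError("dimension mismatch between a, b and Cov(b)")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("Cov(b) must be symmetric")
    Ca = np.diag(se_a**2) if a_cov is None else np.asarray(a_cov, dtype=float)
    effects = a * b
    total = float(effects.sum())
    var = float(a @ C @ a + b @ Ca @ b)
    if var < 0:
        raise ValueError(f"negative delta-method variance ({var}); Cov(b) is not PSD")
    se = float(np.sqrt(var))
    return effects, total, se, (total - Z95 * se, total + Z95 * se)


def percent_mediated(per_mediator_effects, total: float, c_prime: float, floor: float = 0.01):
    """Percent mediated, per mediator and in total.

    ``total%`` is ``100 * total / (c' + total)``; each mediator's share uses
    the same denominator, so the per-mediator percentages sum to the total
    exactly.  The result is flagged unreliable when the total indirect and
    the denominator have opposite signs (suppression) or the denominator's
    magnitude is below ``floor`` (the decomposition then explodes).
    """
    denom = c_prime + total
    if denom == 0:
        raise UndefinedPercentageError("c' + total mediated effect is zero")
    per = 100.0 * np.asarray(per_mediator_effects, dtype=float) / denom
    total_pct = 100.0 * total / denom
    unreliable = bool(np.sign(total) != np.sign(denom) and total != 0) or abs(denom) < floor
    return per, total_pct, unreliable


def classify_mediation(c: float, c_prime: float, total: float,
                       total_significant: bool, c_prime_significant: bool) -> str:
    """Qualitative mediation pattern from the direct and indirect effects.

    inconsistent: significant indirect effect opposing the direct effect's
    sign (suppression); partial: both significant, same sign; full:
    indirect significant, direct not; none: indirect not significant.
    """
    if not total_significant:
        return "none"
    if np.sign(total) != np.sign(c_prime) and c_prime != 0:
        return "inconsistent"
    if c_prime_significant:
        return "partial"
    return "full"


# ---------------------------------------------------------------------------
# results


@dataclass
class SingleMediationResult:
    """One exposure/mediator pair from the single-mediator models."""

    exposure: str
    mediator: str
    a: float
    se_a: float
    b: float
    se_b: float
    effect: float
    se: float
    ci: tuple[float, float]

    @property
    def significant(self) -> bool:
        lo, hi = self.ci
        return lo > 0 or hi < 0


@dataclass
class MultipleMediationResult:
    """Joint multiple-mediator model for one exposure."""

    exposure: str
    mediators: list[str]
    effects: dict[str, float]
    effect_cis: dict[str, tuple[float, float]]
    total: float
    se_total: float
    ci_total: tuple[float, float]
    c: float
    se_c: float
    c_prime: float
    se_c_prime: float
    percent: dict[str, float] | None
    percent_total: float | None
    classification: str
    percent_suppressed: bool

    @property
    def total_significant(self) -> bool:
        lo, hi = self.ci_total
        return lo > 0 or hi < 0

    @property
    def direct_or(self) -> float:
        return float(np.exp(self.c_prime))


@dataclass
class PathEstimates:
    """All path coefficients and uncertainties for one exposure/mediator set."""

    exposure: str
    mediators: list[str]
    a: pd.Series
    se_a: pd.Series
    b: pd.Series
    cov_b: pd.DataFrame
    c: float
    se_c: float
    c_prime: float
    se_c_prime: float
    c_fit: MixedModelFit | None = None
    joint_fit: MixedModelFit | None = None
    a_fits: dict[str, MixedModelFit] = field(default_factory=dict)

    def __post_init__(self):
        if list(self.a.index) != self.mediators or list(self.b.index) != self.mediators:
            raise ValueError("a/b estimates misaligned with the mediator list")


def select_mediators(single_results: list[SingleMediationResult], alpha: float = 0.05):
    """Mediators whose single-model indirect-effect CI excludes zero.

    The CIs carried by the results are 95% intervals; for a different
    ``alpha`` the normal CI is recomputed from the stored SE.
    """
    if not single_results:
        raise ValueError("no candidate mediators supplied")
    from scipy.stats import norm

    z = Z95 if abs(alpha - 0.05) < 1e-12 else float(norm.ppf(1 - alpha / 2))
    keep = []
    for r in single_results:
        lo, hi = r.effect - z * r.se, r.effect + z * r.se
        if lo > 0 or hi < 0:
            keep.append(r.mediator)
    return keep


# ---------------------------------------------------------------------------
# model orchestration


def expand_covariates(data: pd.DataFrame, covariates=DEFAULT_COVARIATES):
    """Expand covariates into numeric model columns.

    ``parent_education`` becomes two dummies against the "<12" reference
    band; everything else is used as-is.  Returns ``(data, columns)`` where
    ``data`` may be a copy carrying the added dummy columns.
    """
    cols: list[str] = []
    out = data
    for cov in covariates:
        if cov == "parent_education":
            if not set(EDU_DUMMIES) <= set(out.columns):
                out = out.copy()
                edu = out["parent_education"].astype(str)
                known = {"<12", "12-13", ">=14"}
                bad = set(edu.dropna().unique()) - known
                if bad:
                    raise ValueError(f"unknown parent_education levels: {sorted(bad)}")
                out["edu_12_13"] = (edu == "12-13").astype(float)
                out["edu_ge14"] = (edu == ">=14").astype(float)
            cols.extend(EDU_DUMMIES)
        else:
            cols.append(cov)
    return out, cols


def estimate_paths(
    data: pd.DataFrame,
    exposure: str,
    mediators=DEFAULT_MEDIATORS,
    covariates=DEFAULT_COVARIATES,
    outcome: str = "sport_participant",
    country_col: str = "country_id",
    school_col: str = "school_id",
    **settings,
) -> PathEstimates:
    """Fit every path model for one exposure and collect the estimates.

    The total effect c comes from ``logit(outcome) ~ exposure + covariates``;
    each a_i from ``mediator_i ~ exposure + covariates`` (identity link); the
    b-vector, its covariance block and the direct effect c' from the joint
    ``logit(outcome) ~ mediators + exposure + covariates`` model.
    """
    mediators = list(mediators)
    data, cov_cols = expand_covariates(data, covariates)
    common = dict(country_col=country_col, school_col=school_col, **settings)

    def _fit(outcome_col, fixed, link):
        try:
            return fit_three_level(data, outcome_col, fixed, link=link, **common)
        except Exception as exc:
            raise type(exc)(f"[{exposure}: {link} model for {outcome_col}] {exc}") from exc

    c_fit = _fit(outcome, [exposure, *cov_cols], "logit")
    a_fits = {m: _fit(m, [exposure, *cov_cols], "identity") for m in mediators}
    joint_fit = _fit(outcome, [*mediators, exposure, *cov_cols], "logit")

    a = pd.Series({m: float(a_fits[m].params[exposure]) for m in mediators})
    se_a = pd.Series({m: float(a_fits[m].se[exposure]) for m in mediators})
    b = joint_fit.params[mediators].astype(float)
    cov_b = joint_fit.cov_params.loc[mediators, mediators].astype(float)
    return PathEstimates(
        exposure=exposure,
        mediators=mediators,
        a=a,
        se_a=se_a,
        b=b,
        cov_b=cov_b,
        c=float(c_fit.params[exposure]),
        se_c=float(c_fit.se[exposure]),
        c_prime=float(joint_fit.params[exposure]),
        se_c_prime=float(joint_fit.se[exposure]),
        c_fit=c_fit,
        joint_fit=joint_fit,
        a_fits=a_fits,
    )


def parametric_total_draws(a, se_a, b, cov_b, n_draws=100_000, rng=None):
    """Monte-Carlo draws of ``sum_i a_i* b_i*`` under the estimated sampling
    distributions (independent normal a's, jointly normal b's).

    A validation alternative to the delta-method SE (non-canonical); its SD
    converges to the delta SE when the relative uncertainties are small.
    """
    rng = np.random.default_rng(rng)
    a = np.asarray(a, float)
    se_a = np.asarray(se_a, float)
    b = np.asarray(b, float)
    C = np.atleast_2d(np.asarray(cov_b, float))
    a_star = rng.normal(a, se_a, size=(n_draws, len(a)))
    b_star = rng.multivariate_normal(b, C, size=n_draws, method="cholesky")
    return (a_star * b_star).sum(axis=1)


# ---------------------------------------------------------------------------
# estimator


class MultilevelMediation(BaseEstimator):
    """Single- and multiple-mediator analysis over a coded cohort table.

    For every exposure the estimator fits the c-path model, the four
    single-mediator analyses, selects the mediators whose single-model
    indirect effect is significant, and (when any survive) fits the joint
    multiple-mediator model with the delta-method total indirect effect,
    percent mediated and a mediation-type classification.

    Parameters
    ----------
    exposures, mediators, covariates : sequences of column names
    outcome : binary outcome column
    alpha : CI level for significance calls (0.05 gives 95% CIs)
    percent_floor : |c' + total| below which percent mediated is flagged
        unreliable
    method, n_quad, max_iter, tol : estimation settings passed to the
        three-level logistic fits

    Attributes (after ``fit``)
    --------------------------
    paths_ : dict exposure -> PathEstimates (joint model, selected mediators)
    single_ : dict exposure -> list of SingleMediationResult
    selected_ : dict exposure -> list of retained mediator names
    multiple_ : dict exposure -> MultipleMediationResult or None (skipped)
    notices_ : list of str, machine-readable warnings
    """

    def __init__(
        self,
        exposures=DEFAULT_EXPOSURES,
        mediators=DEFAULT_MEDIATORS,
        covariates=DEFAULT_COVARIATES,
        outcome="sport_participant",
        country_col="country_id",
        school_col="school_id",
        alpha=0.05,
        percent_floor=0.01,
        method="laplace",
        n_quad=7,
        max_iter=200,
        tol=1e-8,
    ):
        self.exposures = exposures
        self.mediators = mediators
        self.covariates = covariates
        self.outcome = outcome
        self.country_col = country_col
        self.school_col = school_col
        self.alpha = alpha
        self.percent_floor = percent_floor
        self.method = method
        self.n_quad = n_quad
        self.max_iter = max_iter
        self.tol = tol

    # -- internals ----------------------------------------------------------

    def _settings(self):
        return dict(method=self.method, n_quad=self.n_quad,
                    max_iter=self.max_iter, tol=self.tol)

    def _validate(self, data: pd.DataFrame):
        exposures = list(self.exposures)
        mediators = list(self.mediators)
        covariates = list(self.covariates)
        overlap = (set(exposures) & set(mediators)) | (set(exposures) & set(covariates)) | (
            set(mediators) & set(covariates)
        )
        if overlap:
            raise ValueError(f"exposures/mediators/covariates overlap: {sorted(overlap)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        needed = [self.outcome, *exposures, *mediators, self.country_col, self.school_col]
        missing = [c for c in needed if c not in data.columns]
        if missing:
            raise KeyError(f"cohort table lacks columns: {missing}")
        if data[[self.outcome, *exposures, *mediators]].isna().any().any():
            raise ValueError(
                "cohort table contains missing values; assemble the complete-case table first"
            )
        return exposures, mediators, covariates

    def fit(self, X: pd.DataFrame, y=None):
        """Run the full mediation analysis on a complete-case cohort table."""
        exposures, mediators, covariates = self._validate(X)
        data, cov_cols = expand_covariates(X, covariates)
        settings = self._settings()
        common = dict(country_col=self.country_col, school_col=self.school_col, **settings)

        self.paths_ = {}
        self.single_ = {}
        self.selected_ = {}
        self.multiple_ = {}
        self.c_fits_ = {}
        self.notices_ = []

        for exposure in exposures:
            c_fit = fit_three_level(
                data, self.outcome, [exposure, *cov_cols], link="logit", **common
            )
            self.c_fits_[exposure] = c_fit
            c = float(c_fit.params[exposure])
            se_c = float(c_fit.se[exposure])

            a_fits = {
                m: fit_three_level(data, m, [exposure, *cov_cols], link="identity", **common)
                for m in mediators
            }
            singles = []
            for m in mediators:
                b_fit = fit_three_level(
                    data, self.outcome, [m, exposure, *cov_cols], link="logit", **common
                )
                a_m = float(a_fits[m].params[exposure])
                se_a_m = float(a_fits[m].se[exposure])
                b_m = float(b_fit.params[m])
                se_b_m = float(b_fit.se[m])
                effect, se, ci = sobel(a_m, se_a_m, b_m, se_b_m)
                singles.append(
                    SingleMediationResult(exposure, m, a_m, se_a_m, b_m, se_b_m, effect, se, ci)
                )
            self.single_[exposure] = singles

            selected = select_mediators(singles, self.alpha)
            self.selected_[exposure] = selected
            if not selected:
                self.multiple_[exposure] = None
                self.notices_.append(
                    f"{exposure}: no significant single-model mediators; "
                    "multiple mediation model skipped"
                )
                log.info(self.notices_[-1])
                continue

            joint_fit = fit_three_level(
                data, self.outcome, [*selected, exposure, *cov_cols], link="logit", **common
            )
            a = pd.Series({m: float(a_fits[m].params[exposure]) for m in selected})
            se_a = pd.Series({m: float(a_fits[m].se[exposure]) for m in selected})
            b = joint_fit.params[selected].astype(float)
            cov_b = joint_fit.cov_params.loc[selected, selected].astype(float)
            paths = PathEstimates(
                exposure=exposure,
                mediators=selected,
                a=a,
                se_a=se_a,
                b=b,
                cov_b=cov_b,
                c=c,
                se_c=se_c,
                c_prime=float(joint_fit.params[exposure]),
                se_c_prime=float(joint_fit.se[exposure]),
                c_fit=c_fit,
                joint_fit=joint_fit,
                a_fits={m: a_fits[m] for m in selected},
            )
            self.paths_[exposure] = paths
            self.multiple_[exposure] = self._multiple_result(paths, joint_fit)

        return self

    def _multiple_result(self, paths: PathEstimates, joint_fit) -> MultipleMediationResult:
        effects, total, se_total, ci_total = total_mediated(
            paths.a.to_numpy(), paths.se_a.to_numpy(), paths.b.to_numpy(), paths.cov_b.to_numpy()
        )
        effect_cis = {}
        for i, m in enumerate(paths.mediators):
            _, se_i, ci_i = sobel(
                paths.a.iloc[i],
                paths.se_a.iloc[i],
                paths.b.iloc[i],
                float(np.sqrt(paths.cov_b.iloc[i, i])),
            )
            effect_cis[m] = ci_i
        total_sig = ci_total[0] > 0 or ci_total[1] < 0
        cp_wald = wald_test(joint_fit, paths.exposure)
        cp_sig = cp_wald.ci[0] > 0 or cp_wald.ci[1] < 0
        label = classify_mediation(paths.c, paths.c_prime, total, total_sig, cp_sig)

        per_pct = total_pct = None
        suppressed = label == "inconsistent"
        if not suppressed:
            try:
                per, total_pct, unreliable = percent_mediated(
                    effects, total, paths.c_prime, self.percent_floor
                )
                if unreliable:
                    suppressed = True
                    self.notices_.append(
                        f"{paths.exposure}: percent mediated unreliable "
                        "(denominator near zero or sign-inconsistent); suppressed"
                    )
                else:
                    per_pct = dict(zip(paths.mediators, per.tolist()))
            except UndefinedPercentageError:
                suppressed = True
                self.notices_.append(f"{paths.exposure}: percent mediated undefined; suppressed")
        else:
            self.notices_.append(
                f"{paths.exposure}: inconsistent mediation (direct and indirect "
                "effects oppose); percent mediated suppressed"
            )
        if suppressed:
            per_pct = total_pct = None

        return MultipleMediationResult(
            exposure=paths.exposure,
            mediators=paths.mediators,
            effects=dict(zip(paths.mediators, effects.tolist())),
            effect_cis=effect_cis,
            total=total,
            se_total=se_total,
            ci_total=ci_total,
            c=paths.c,
            se_c=paths.se_c,
            c_prime=paths.c_prime,
            se_c_prime=paths.se_c_prime,
            percent=per_pct,
            percent_total=total_pct,
            classification=label,
            percent_suppressed=suppressed,
        )

    # -- tabular views ------------------------------------------------------

    def total_direct_table(self) -> pd.DataFrame:
        """Total and direct effects as odds ratios with 95% CIs."""
        rows = []
        for exposure, c_fit in self.c_fits_.items():
            w = wald_test(c_fit, exposure)
            row = {
                "exposure": exposure,
                "total_OR": np.exp(w.estimate),
                "total_ci_low": np.exp(w.ci[0]),
                "total_ci_high": np.exp(w.ci[1]),
            }
            res = self.multiple_.get(exposure)
            if res is not None:
                row["direct_OR"] = np.exp(res.c_prime)
                row["direct_ci_low"] = np.exp(res.c_prime - Z95 * res.se_c_prime)
                row["direct_ci_high"] = np.exp(res.c_prime + Z95 * res.se_c_prime)
            rows.append(row)
        return pd.DataFrame(rows).set_index("exposure")

    def single_table(self) -> pd.DataFrame:
        rows = []
        for exposure, singles in self.single_.items():
            for r in singles:
                rows.append(
                    {
                        "exposure": exposure,
                        "mediator": r.mediator,
                        "a": r.a,
                        "se_a": r.se_a,
                        "b_OR": np.exp(r.b),
                        "effect": r.effect,
                        "se": r.se,
                        "ci_low": r.ci[0],
                        "ci_high": r.ci[1],
                        "significant": r.significant,
                    }
                )
        return pd.DataFrame(rows)

    def multiple_table(self) -> pd.DataFrame:
        rows = []
        for exposure, res in self.multiple_.items():
            if res is None:
                continue
            for m in res.mediators:
                rows.append(
                    {
                        "exposure": exposure,
                        "mediator": m,
                        "effect": res.effects[m],
                        "ci_low": res.effect_cis[m][0],
                        "ci_high": res.effect_cis[m][1],
                        "percent": None if res.percent is None else res.percent[m],
                    }
                )
            rows.append(
                {
                    "exposure": exposure,
                    "mediator": "(total)",
                    "effect": res.total,
                    "ci_low": res.ci_total[0],
                    "ci_high": res.ci_total[1],
                    "percent": res.percent_total,
                }
            )
        df = pd.DataFrame(rows)
        if not df.empty:
            df["percent"] = df["percent"].astype(object).where(df["percent"].notna(), "suppressed")
        return df
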