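"""Synthetic three-level cohorts with known mediation structure.

Children are nested in schools nested in countries.  The generator emulates
the ENERGY-style survey layout: seven family-environment exposures on their
survey grids, four cognition mediators on the five-point -2..2 grid, binary
sports participation, and the covariates sex, age and parental education.

Generative model
----------------
* exposures: truncated normals on the instrument bounds, snapped to the
  response grid; the latent (mu, sigma) are calibrated numerically so the
  *observed* marginal mean/SD match the requested targets.
* mediator i: ``intercept_i + sum_k a_ik x_k + gamma_i sex + u_country +
  u_school + eps``, rounded to integers and clipped to [-2, 2]; the
  intercept and residual SD are calibrated so the observed grid moments
  match the requested targets.
* outcome: Bernoulli with ``logit p = b0 + sum_k c'_k x_k + sum_i b_i m_i +
  covariate effects + u_country + u_school`` using the *observed* (gridded)
  mediators; ``b0`` is calibrated via a logit-normal approximation to hit
  the target participation prevalence.
* sport hours: participants draw a truncated normal on [0.5, 10] snapped to
  the half-hour grid; non-participants are 0 (so participation == hours >=
  0.5 holds by construction).

Randomness: one root seed; every column/level draws from its own named
substream (seeded by ``[root_seed, crc32(name)]``), so adding a column does
not perturb the others.
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from . import reference

__all__ = [
    "ExposureSpec",
    "MediatorSpec",
    "SyntheticTruth",
    "generate_cohort",
    "default_energy_truth",
    "recovery_truth",
    "null_truth",
    "truth_to_yaml",
    "truth_from_yaml",
    "true_mediated_effects",
]

#: logit-normal moment constant: E[expit(N(mu, s^2))] ~ expit(mu / sqrt(1 + K^2 s^2))
_LOGIT_K = 16.0 * math.sqrt(3.0) / (15.0 * math.pi)

MEDIATOR_GRID = np.arange(-2.0, 2.01, 1.0)

SURVEY_GRIDS = {
    "equipment": tuple(np.arange(0.0, 8.01, 1.0)),
    "financial": (0.0, 1.0, 2.0, 3.0, 4.0),
    "logistic": (0.0, 1.0, 2.0, 3.0, 4.0),
    "emotional": (0.0, 1.0, 2.0, 3.0, 4.0),
    "reinforcement": (0.0, 1.0, 2.0, 3.0, 4.0),
    "modelling": tuple(np.arange(0.0, 10.01, 0.5)),
    "coparticipation": (0.0, 0.5, 1.0, 3.0, 5.5, 7.0),
}


class TruthConfigError(ValueError):
    """The generative configuration is infeasible (bounds, variances, counts)."""


@dataclass(frozen=True)
class ExposureSpec:
    """Target observed marginal for one exposure on its survey grid."""

    mean: float
    sd: float
    lower: float
    upper: float
    grid: tuple[float, ...]

    def __post_init__(self):
        if not self.lower < self.upper:
            raise TruthConfigError(f"bounds not ordered: {self.lower} >= {self.upper}")
        if self.sd <= 0:
            raise TruthConfigError("exposure SD must be positive")


@dataclass(frozen=True)
class MediatorSpec:
    """Target observed marginal for one mediator on the -2..2 grid."""

    mean: float
    sd: float


@dataclass
class SyntheticTruth:
    """Full generative parameterization of a synthetic cohort.

    ``a_matrix[mediator][exposure]`` are the true exposure->mediator linear
    coefficients, ``b_vector[mediator]`` the mediator->outcome log-odds and
    ``c_prime[exposure]`` the direct exposure->outcome log-odds.  Variance
    components are random-intercept SDs (not variances).  ``outcome_intercept``
    may be None, in which case it is calibrated to ``target_prevalence``.
    """

    n_countries: int = 7
    schools_per_country: int = 25
    children_per_school: int = 28
    exposures: dict[str, ExposureSpec] = field(default_factory=dict)
    mediators: dict[str, MediatorSpec] = field(default_factory=dict)
    a_matrix: dict[str, dict[str, float]] = field(default_factory=dict)
    b_vector: dict[str, float] = field(default_factory=dict)
    c_prime: dict[str, float] = field(default_factory=dict)
    outcome_intercept: float | None = None
    target_prevalence: float = 0.534
    # covariate distributions
    boy_prob: float = 0.46
    age_mean: float = 11.6
    age_sd: float = 0.7
    education_probs: tuple[float, float, float] = (0.165, 0.237, 0.598)
    # covariate effects on the outcome logit (boy, per year of age, and the
    # two education contrasts vs "<12")
    sex_effect_outcome: float = 0.6
    age_effect_outcome: float = -0.15
    education_effects_outcome: tuple[float, float] = (0.10, 0.25)
    # sex (boy) effect on each mediator's latent scale
    sex_effect_mediators: dict[str, float] = field(default_factory=dict)
    # random-intercept SDs
    mediator_country_sd: float = 0.17
    mediator_school_sd: float = 0.22
    outcome_country_sd: float = 0.33
    outcome_school_sd: float = 0.42
    # hours of sport among participants (before snapping to the 0.5 grid)
    hours_mean: float = 3.5
    hours_sd: float = 2.5
    # independent per-column missingness
    missing_rate: float = 0.0
    missing_columns: tuple[str, ...] = ()
    rng_seed: int = 20130203

    def __post_init__(self):
        for nm, v in [
            ("n_countries", self.n_countries),
            ("schools_per_country", self.schools_per_country),
            ("children_per_school", self.children_per_school),
        ]:
            if v < 1:
                raise TruthConfigError(f"{nm} must be >= 1, got {v}")
        for nm in (
            "mediator_country_sd",
            "mediator_school_sd",
            "outcome_country_sd",
            "outcome_school_sd",
        ):
            if getattr(self, nm) < 0:
                raise TruthConfigError(f"{nm} must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise TruthConfigError("missing_rate must be in [0, 1)")

    @property
    def n_children(self) -> int:
        return self.n_countries * self.schools_per_country * self.children_per_school

    @property
    def exposure_names(self) -> list[str]:
        return list(self.exposures)

    @property
    def mediator_names(self) -> list[str]:
        return list(self.mediators)


# ---------------------------------------------------------------------------
# calibration helpers


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


#: weight on the mean residual during moment calibration; some published
#: (mean, SD) pairs are unattainable for a truncated/gridded normal, and the
#: mean must win the compromise (downstream prevalence calibration and the
#: descriptive checks key on means)
_MEAN_WEIGHT = 50.0


def _truncnorm_params(mean: float, sd: float, lower: float, upper: float):
    """Latent (mu, sigma) whose truncation to [lower, upper] has the target moments."""

    def resid(p):
        mu, logsig = p
        sig = math.exp(logsig)
        a, b = (lower - mu) / sig, (upper - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [_MEAN_WEIGHT * (m - mean), math.sqrt(max(v, 1e-12)) - sd]

    sol = optimize.least_squares(resid, [mean, math.log(sd)], xtol=1e-12, ftol=1e-12)
    mu, sig = sol.x[0], math.exp(sol.x[1])
    return mu, sig


def _grid_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Observed mean/SD of round-then-clip(N(mu, sigma^2)) on the -2..2 grid."""
    cuts = np.array([-1.5, -0.5, 0.5, 1.5])
    cdf = stats.norm.cdf(cuts, loc=mu, scale=sigma)
    probs = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    m = float(MEDIATOR_GRID @ probs)
    v = float((MEDIATOR_GRID - m) ** 2 @ probs)
    return m, math.sqrt(max(v, 1e-12))


def _gridnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Latent (mu, sigma) whose gridded moments best match the targets.

    Near the scale ends not every (mean, SD) pair is attainable on the
    five-point grid; the least-squares solution is accepted as-is.
    """

    def resid(p):
        m, s = _grid_moments(p[0], math.exp(p[1]))
        return [_MEAN_WEIGHT * (m - mean), s - sd]

    sol = optimize.least_squares(resid, [mean, math.log(max(sd, 0.2))], xtol=1e-12)
    return sol.x[0], math.exp(sol.x[1])


def _snap(values: np.ndarray, grid) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    idx = np.argmin(np.abs(values[:, None] - grid[None, :]), axis=1)
    return grid[idx]


def _calibrate_intercept(truth: SyntheticTruth) -> float:
    """Outcome intercept hitting the target prevalence (logit-normal moment match)."""
    exp_names = truth.exposure_names
    med_names = truth.mediator_names
    mu_x = np.array([truth.exposures[e].mean for e in exp_names])
    sd_x = np.array([truth.exposures[e].sd for e in exp_names])
    c = np.array([truth.c_prime.get(e, 0.0) for e in exp_names])
    b = np.array([truth.b_vector.get(m, 0.0) for m in med_names])
    A = np.array(
        [[truth.a_matrix.get(m, {}).get(e, 0.0) for e in exp_names] for m in med_names]
    )
    sex_med = np.array([truth.sex_effect_mediators.get(m, 0.0) for m in med_names])
    mu_m = np.array([truth.mediators[m].mean for m in med_names])
    sd_m = np.array([truth.mediators[m].sd for m in med_names])

    p_boy = truth.boy_prob
    e2, e3 = truth.education_effects_outcome
    p1, p2, p3 = truth.education_probs
    edu_mean = e2 * p2 + e3 * p3
    edu_var = e2**2 * p2 + e3**2 * p3 - edu_mean**2

    mean_lp = (
        c @ mu_x
        + b @ mu_m
        + truth.sex_effect_outcome * p_boy
        + truth.age_effect_outcome * truth.age_mean
        + edu_mean
    )
    # exposure channel (direct + via mediators), then mediator residual part
    chan = c + b @ A
    med_resid_var = np.maximum(
        sd_m**2 - (A**2) @ (sd_x**2) - sex_med**2 * p_boy * (1 - p_boy), 0.0
    )
    sex_total = truth.sex_effect_outcome + b @ sex_med
    var_lp = (
        chan**2 @ sd_x**2
        + b**2 @ med_resid_var
        + sex_total**2 * p_boy * (1 - p_boy)
        + truth.age_effect_outcome**2 * truth.age_sd**2
        + edu_var
        + truth.outcome_country_sd**2
        + truth.outcome_school_sd**2
    )
    target_logit = math.log(truth.target_prevalence / (1 - truth.target_prevalence))
    return target_logit * math.sqrt(1.0 + _LOGIT_K**2 * var_lp) - mean_lp


# ---------------------------------------------------------------------------
# generation


def generate_cohort(truth: SyntheticTruth, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort table from ``truth``.

    ``seed`` overrides ``truth.rng_seed``; the same (truth, seed) pair always
    yields an identical table.  Output columns match the coded analytic
    layout (identifiers, covariates, exposures, mediators, sport outcome).
    """
    seed = truth.rng_seed if seed is None else int(seed)
    n_c, n_s, n_k = truth.n_countries, truth.schools_per_country, truth.children_per_school
    n = truth.n_children
    country_idx = np.repeat(np.arange(n_c), n_s * n_k)
    school_idx = np.repeat(np.arange(n_c * n_s), n_k)

    df = pd.DataFrame(
        {
            "child_id": [f"ch{i:05d}" for i in range(n)],
            "school_id": [f"c{c}:s{s % n_s}" for c, s in zip(country_idx, school_idx)],
            "country_id": [f"c{c}" for c in country_idx],
        }
    )

    # covariates
    df["sex"] = (_rng(seed, "sex").random(n) < truth.boy_prob).astype(int)
    age = _rng(seed, "age").normal(truth.age_mean, truth.age_sd, n)
    df["age_years"] = np.clip(age, 9.5, 13.5).round(1)
    edu_levels = np.array(["<12", "12-13", ">=14"])
    probs = np.asarray(truth.education_probs, dtype=float)
    df["parent_education"] = edu_levels[
        _rng(seed, "education").choice(3, size=n, p=probs / probs.sum())
    ]

    # exposures
    for name, spec in truth.exposures.items():
        mu, sig = _truncnorm_params(spec.mean, spec.sd, spec.lower, spec.upper)
        a, b = (spec.lower - mu) / sig, (spec.upper - mu) / sig
        draws = stats.truncnorm.rvs(
            a, b, loc=mu, scale=sig, size=n, random_state=_rng(seed, f"exposure:{name}")
        )
        df[name] = _snap(draws, spec.grid)

    X = df[truth.exposure_names].to_numpy(float)

    # mediators: latent linear predictor + nested intercepts + residual
    boy = df["sex"].to_numpy(float)
    mediators_obs = {}
    for name, spec in truth.mediators.items():
        a_row = np.array(
            [truth.a_matrix.get(name, {}).get(e, 0.0) for e in truth.exposure_names]
        )
        sex_eff = truth.sex_effect_mediators.get(name, 0.0)
        lp_part = X @ a_row + sex_eff * boy
        lp_var = a_row**2 @ np.array([truth.exposures[e].sd for e in truth.exposure_names]) ** 2
        lp_var += sex_eff**2 * truth.boy_prob * (1 - truth.boy_prob)
        vc_var = truth.mediator_country_sd**2 + truth.mediator_school_sd**2
        mu_lat, sd_lat = _gridnorm_params(spec.mean, spec.sd)
        resid_var = sd_lat**2 - lp_var - vc_var
        if resid_var <= 0:
            raise TruthConfigError(
                f"mediator {name!r}: systematic + group variance exceeds the "
                f"calibrated latent variance ({sd_lat**2:.3f})"
            )
        lp_mean = a_row @ np.array([truth.exposures[e].mean for e in truth.exposure_names])
        lp_mean += sex_eff * truth.boy_prob
        intercept = mu_lat - lp_mean
        rng_re = _rng(seed, f"mediator_re:{name}")
        u_c = rng_re.normal(0.0, truth.mediator_country_sd, n_c)
        u_s = rng_re.normal(0.0, truth.mediator_school_sd, n_c * n_s)
        eps = _rng(seed, f"mediator_eps:{name}").normal(0.0, math.sqrt(resid_var), n)
        latent = intercept + lp_part + u_c[country_idx] + u_s[school_idx] + eps
        obs = np.clip(np.round(latent), -2, 2)
        mediators_obs[name] = obs
        df[name] = obs

    # outcome
    b0 = truth.outcome_intercept
    if b0 is None:
        b0 = _calibrate_intercept(truth)
    c_vec = np.array([truth.c_prime.get(e, 0.0) for e in truth.exposure_names])
    logit = b0 + X @ c_vec
    for name in truth.mediator_names:
        logit += truth.b_vector.get(name, 0.0) * mediators_obs[name]
    e2, e3 = truth.education_effects_outcome
    edu = df["parent_education"].to_numpy()
    logit += (
        truth.sex_effect_outcome * boy
        + truth.age_effect_outcome * df["age_years"].to_numpy()
        + e2 * (edu == "12-13")
        + e3 * (edu == ">=14")
    )
    rng_re = _rng(seed, "outcome_re")
    logit += rng_re.normal(0.0, truth.outcome_country_sd, n_c)[country_idx]
    logit += rng_re.normal(0.0, truth.outcome_school_sd, n_c * n_s)[school_idx]
    p = 1.0 / (1.0 + np.exp(-logit))
    participant = (_rng(seed, "outcome").random(n) < p).astype(int)
    df["sport_participant"] = participant

    hours_grid = np.arange(0.5, 10.01, 0.5)
    raw_hours = stats.truncnorm.rvs(
        (0.5 - truth.hours_mean) / truth.hours_sd,
        (10.0 - truth.hours_mean) / truth.hours_sd,
        loc=truth.hours_mean,
        scale=truth.hours_sd,
        size=n,
        random_state=_rng(seed, "hours"),
    )
    df["sport_hours"] = np.where(participant == 1, _snap(raw_hours, hours_grid), 0.0)

    # missingness, independent per column
    for col in truth.missing_columns:
        if truth.missing_rate <= 0 or col not in df.columns:
            continue
        mask = _rng(seed, f"missing:{col}").random(n) < truth.missing_rate
        df[col] = df[col].mask(mask)

    return df


def rounding_attenuation(truth: SyntheticTruth, mediator: str) -> float:
    """Slope attenuation induced by the five-point mediator discretization.

    The observed mediator is ``clip(round(latent))``, a step function with
    unit jumps at the interior cutpoints -1.5, -0.5, 0.5, 1.5 (everything
    beyond +/-1.5 lands in an end category).  For a Gaussian latent scale,
    Stein's lemma gives the regression slope of the observed on the latent
    predictor as the latent slope times ``sum_k phi(k; mu_lat, sd_lat)``
    over those cutpoints.  This factor is what any fitted a-path targets.
    """
    spec = truth.mediators[mediator]
    mu_lat, sd_lat = _gridnorm_params(spec.mean, spec.sd)
    cuts = np.array([-1.5, -0.5, 0.5, 1.5])
    return float(stats.norm.pdf(cuts, loc=mu_lat, scale=sd_lat).sum())


def true_mediated_effects(
    truth: SyntheticTruth, exposure: str, observable: bool = False
) -> dict[str, float]:
    """True per-mediator indirect effects a_i * b_i for one exposure.

    With ``observable=True`` each a_i is multiplied by the mediator's
    :func:`rounding_attenuation` factor, giving the indirect effect of the
    *observed* (gridded) mediator -- the estimand of the fitted models.
    """
    out = {}
    for m in truth.mediator_names:
        a = truth.a_matrix.get(m, {}).get(exposure, 0.0)
        if observable:
            a *= rounding_attenuation(truth, m)
        out[m] = a * truth.b_vector.get(m, 0.0)
    return out


# ---------------------------------------------------------------------------
# documented default truths


def _marginal_specs():
    exposures = {}
    for name in reference.EXPOSURES:
        m = reference.MARGINALS[name]
        lo, hi = m["bounds"]
        exposures[name] = ExposureSpec(m["mean"], m["sd"], lo, hi, SURVEY_GRIDS[name])
    mediators = {
        name: MediatorSpec(reference.MARGINALS[name]["mean"], reference.MARGINALS[name]["sd"])
        for name in reference.MEDIATORS
    }
    return exposures, mediators


def default_energy_truth(seed: int = 20130203, missing_rate: float = 0.02) -> SyntheticTruth:
    """ENERGY-like default cohort: published marginals, plausible path values.

    Marginal means/SDs of all exposures, mediators and covariates target the
    published descriptives, and the outcome intercept is calibrated so the
    participation prevalence lands near 53.4%.  The path coefficients mirror
    the order of magnitude of the published estimates (a-paths 0.006-0.09,
    b-paths equal to the logs of the published multiple-model odds ratios,
    c'-paths the logs of the published direct-effect odds ratios); they are
    chosen for testability, not as estimates of the real study's truth.
    """
    exposures, mediators = _marginal_specs()
    a_matrix = {
        med: {exp: reference.SINGLE_MODELS[exp][med].a for exp in reference.EXPOSURES}
        for med in reference.MEDIATORS
    }
    b_vector = {
        "attitude": math.log(1.35),
        "belief": math.log(1.07),
        "enjoyment": math.log(1.60),
        "pbc": math.log(1.85),
    }
    c_prime = {
        exp: math.log(reference.TOTAL_DIRECT[exp].direct_or) for exp in reference.EXPOSURES
    }
    parent_cols = (
        "financial",
        "logistic",
        "emotional",
        "reinforcement",
        "coparticipation",
        "modelling",
        "parent_education",
    )
    return SyntheticTruth(
        exposures=exposures,
        mediators=mediators,
        a_matrix=a_matrix,
        b_vector=b_vector,
        c_prime=c_prime,
        sex_effect_mediators={"attitude": 0.1, "belief": 0.0, "enjoyment": 0.1, "pbc": 0.2},
        missing_rate=missing_rate,
        missing_columns=parent_cols if missing_rate > 0 else (),
        rng_seed=seed,
    )


def recovery_truth(seed: int = 1, schools_per_country: int = 10, children_per_school: int = 43) -> SyntheticTruth:
    """Documented truth for estimator-calibration studies.

    Uses a single active exposure (financial support) with centred
    mediators (mean 0, SD 1.1 on the five-point grid) so that grid
    rounding/clipping barely attenuates the latent paths, and path values
    large enough that the per-mediator indirect effects of interest exceed
    0.05 on the log-odds scale.
    """
    exposures, _ = _marginal_specs()
    mediators = {m: MediatorSpec(0.0, 1.1) for m in reference.MEDIATORS}
    a_fin = {"attitude": 0.12, "belief": 0.10, "enjoyment": 0.15, "pbc": 0.18}
    a_matrix = {m: {"financial": a_fin[m]} for m in reference.MEDIATORS}
    b_vector = {"attitude": 0.35, "belief": 0.10, "enjoyment": 0.50, "pbc": 0.60}
    return SyntheticTruth(
        schools_per_country=schools_per_country,
        children_per_school=children_per_school,
        exposures={"financial": exposures["financial"]},
        mediators=mediators,
        a_matrix=a_matrix,
        b_vector=b_vector,
        c_prime={"financial": 0.20},
        target_prevalence=0.534,
        sex_effect_mediators={m: 0.0 for m in reference.MEDIATORS},
        rng_seed=seed,
    )


def null_truth(seed: int = 1, schools_per_country: int = 10, children_per_school: int = 20) -> SyntheticTruth:
    """Recovery-style truth with every a-path zero (no indirect channel)."""
    t = recovery_truth(seed, schools_per_country, children_per_school)
    t.a_matrix = {m: {"financial": 0.0} for m in t.mediator_names}
    return t


# ---------------------------------------------------------------------------
# structured-text round trip


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def truth_to_yaml(truth: SyntheticTruth) -> str:
    d = dataclasses.asdict(truth)
    d["exposures"] = {k: dataclasses.asdict(v) for k, v in truth.exposures.items()}
    d["mediators"] = {k: dataclasses.asdict(v) for k, v in truth.mediators.items()}
    return yaml.safe_dump(_plain(d), sort_keys=False)


def truth_from_yaml(text: str) -> SyntheticTruth:
    d = yaml.safe_load(text)
    d["exposures"] = {
        k: ExposureSpec(
            v["mean"], v["sd"], v["lower"], v["upper"], tuple(float(g) for g in v["grid"])
        )
        for k, v in d.get("exposures", {}).items()
    }
    d["mediators"] = {
        k: MediatorSpec(v["mean"], v["sd"]) for k, v in d.get("mediators", {}).items()
    }
    for key in ("education_probs", "education_effects_outcome", "missing_columns"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SyntheticTruth(**d)
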