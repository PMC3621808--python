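"""Published ENERGY-survey estimates used as worked-example inputs.

The ENERGY cross-European school survey (seven countries, 10-12 year-old
children) examined whether four cognitions -- attitude, health beliefs,
enjoyment and perceived behavioural control (PBC) -- mediate associations
between seven family-environment variables and participation in >= 30
minutes/week of sport.  The raw survey data are not publicly deposited, so
this module records the *published* estimates: marginal means/SDs of the
analysis variables (targets for the synthetic-cohort generator), total and
direct effect odds ratios, and the single/multiple mediation-model path
estimates and mediated effects.

These numbers are inputs for worked examples and arithmetic identity checks
(e.g. the total mediated effect must equal the sum of the per-mediator
effects); the package never tunes its own computations toward them.
"""

from __future__ import annotations

from dataclasses import dataclass


EXPOSURES = (
    "equipment",
    "financial",
    "logistic",
    "emotional",
    "reinforcement",
    "modelling",
    "coparticipation",
)

MEDIATORS = ("attitude", "belief", "enjoyment", "pbc")

#: analytic-sample size of the published analysis
N_ANALYTIC = 4952

#: marginal mean, SD and legal bounds of each analysis variable in the
#: published descriptive table (total sample), plus the participation rate
MARGINALS = {
    "age_years": {"mean": 11.6, "sd": 0.7, "bounds": (10.0, 13.0)},
    "equipment": {"mean": 5.3, "sd": 2.0, "bounds": (0.0, 8.0)},
    "financial": {"mean": 2.9, "sd": 1.3, "bounds": (0.0, 4.0)},
    "logistic": {"mean": 2.7, "sd": 1.3, "bounds": (0.0, 4.0)},
    "emotional": {"mean": 3.4, "sd": 1.0, "bounds": (0.0, 4.0)},
    "reinforcement": {"mean": 2.9, "sd": 1.1, "bounds": (0.0, 4.0)},
    "modelling": {"mean": 2.6, "sd": 2.5, "bounds": (0.0, 10.0)},
    "coparticipation": {"mean": 1.4, "sd": 1.4, "bounds": (0.0, 7.0)},
    "attitude": {"mean": 1.9, "sd": 0.4, "bounds": (-2.0, 2.0)},
    "belief": {"mean": 1.0, "sd": 1.3, "bounds": (-2.0, 2.0)},
    "enjoyment": {"mean": 1.8, "sd": 0.6, "bounds": (-2.0, 2.0)},
    "pbc": {"mean": 1.4, "sd": 0.8, "bounds": (-2.0, 2.0)},
}

#: participation in >= 30 min/week of sport, total sample (percent)
PARTICIPATION_PCT = 53.4

#: proportion of girls in the analytic sample
GIRL_PCT = 54.0

#: responding parent's education, proportions of the three bands (percent)
EDUCATION_PCT = {"<12": 16.5, "12-13": 23.7, ">=14": 59.8}


@dataclass(frozen=True)
class TotalDirectOR:
    """Published total (c) and direct (c') effect odds ratios with 95% CIs."""

    total_or: float
    total_ci: tuple[float, float]
    direct_or: float
    direct_ci: tuple[float, float]


TOTAL_DIRECT = {
    "equipment": TotalDirectOR(1.16, (1.12, 1.20), 1.11, (1.08, 1.16)),
    "financial": TotalDirectOR(1.53, (1.45, 1.61), 1.44, (1.37, 1.52)),
    "logistic": TotalDirectOR(1.47, (1.40, 1.55), 1.40, (1.33, 1.47)),
    "emotional": TotalDirectOR(1.51, (1.40, 1.62), 1.39, (1.29, 1.50)),
    "reinforcement": TotalDirectOR(1.03, (0.98, 1.09), 1.01, (0.95, 1.07)),
    "modelling": TotalDirectOR(1.07, (1.04, 1.10), 1.06, (1.03, 1.08)),
    "coparticipation": TotalDirectOR(1.01, (0.97, 1.06), 0.99, (0.94, 1.04)),
}


@dataclass(frozen=True)
class SingleModelRow:
    """Single-mediator model row: a-path, b-path OR, mediated effect a*b."""

    a: float
    a_ci: tuple[float, float]
    b_or: float
    b_or_ci: tuple[float, float]
    mediated: float
    mediated_ci: tuple[float, float]


@dataclass(frozen=True)
class MultipleModelRow:
    """Multiple-mediator model row; ``None`` where the mediator was excluded."""

    b_or: float | None
    b_or_ci: tuple[float, float] | None
    mediated: float | None
    mediated_ci: tuple[float, float] | None
    percent: float | None  # None when excluded or suppressed


# Single mediation models: one entry per exposure, one row per mediator.
SINGLE_MODELS = {
    "equipment": {
        "attitude": SingleModelRow(0.018, (0.012, 0.023), 2.42, (2.05, 2.87), 0.024, (0.017, 0.031)),
        "belief": SingleModelRow(0.039, (0.019, 0.059), 1.11, (1.06, 1.16), 0.005, (0.002, 0.008)),
        "enjoyment": SingleModelRow(0.020, (0.012, 0.028), 2.51, (2.20, 2.87), 0.031, (0.022, 0.040)),
        "pbc": SingleModelRow(0.034, (0.022, 0.046), 2.14, (1.97, 2.33), 0.036, (0.026, 0.047)),
    },
    "financial": {
        "attitude": SingleModelRow(0.042, (0.033, 0.051), 2.27, (1.91, 2.69), 0.034, (0.024, 0.044)),
        "belief": SingleModelRow(0.041, (0.013, 0.069), 1.11, (1.06, 1.17), 0.004, (0.001, 0.008)),
        "enjoyment": SingleModelRow(0.079, (0.067, 0.092), 2.29, (2.00, 2.61), 0.066, (0.051, 0.080)),
        "pbc": SingleModelRow(0.087, (0.069, 0.105), 2.08, (1.91, 2.26), 0.064, (0.049, 0.079)),
    },
    "logistic": {
        "attitude": SingleModelRow(0.036, (0.027, 0.045), 2.35, (1.98, 2.79), 0.031, (0.021, 0.041)),
        "belief": SingleModelRow(0.032, (0.003, 0.060), 1.12, (1.07, 1.17), 0.004, (0.000, 0.007)),
        "enjoyment": SingleModelRow(0.070, (0.057, 0.082), 2.37, (2.07, 2.71), 0.060, (0.046, 0.074)),
        "pbc": SingleModelRow(0.087, (0.070, 0.105), 2.09, (1.92, 2.27), 0.064, (0.049, 0.079)),
    },
    "emotional": {
        "attitude": SingleModelRow(0.035, (0.023, 0.047), 2.43, (2.05, 2.87), 0.031, (0.019, 0.043)),
        "belief": SingleModelRow(0.059, (0.021, 0.096), 1.11, (1.06, 1.17), 0.006, (0.001, 0.011)),
        "enjoyment": SingleModelRow(0.062, (0.046, 0.079), 2.47, (2.16, 2.82), 0.057, (0.039, 0.074)),
        "pbc": SingleModelRow(0.088, (0.064, 0.112), 2.12, (1.95, 2.30), 0.066, (0.046, 0.085)),
    },
    "reinforcement": {
        "attitude": SingleModelRow(0.010, (-0.001, 0.020), 2.57, (2.17, 3.04), 0.009, (-0.001, 0.019)),
        "belief": SingleModelRow(0.016, (-0.018, 0.050), 1.12, (1.07, 1.18), 0.002, (-0.002, 0.006)),
        "enjoyment": SingleModelRow(0.016, (0.001, 0.031), 2.59, (2.27, 2.96), 0.015, (0.001, 0.030)),
        "pbc": SingleModelRow(0.025, (0.003, 0.047), 2.19, (2.01, 2.37), 0.020, (0.003, 0.037)),
    },
    "modelling": {
        "attitude": SingleModelRow(0.007, (0.002, 0.011), 2.55, (2.15, 3.01), 0.006, (0.002, 0.011)),
        "belief": SingleModelRow(0.030, (0.015, 0.045), 1.12, (1.07, 1.17), 0.003, (0.001, 0.005)),
        "enjoyment": SingleModelRow(0.007, (0.001, 0.013), 2.58, (2.26, 2.95), 0.007, (0.001, 0.013)),
        "pbc": SingleModelRow(0.021, (0.012, 0.031), 2.17, (2.00, 2.36), 0.017, (0.009, 0.024)),
    },
    "coparticipation": {
        "attitude": SingleModelRow(0.006, (-0.002, 0.014), 2.57, (2.18, 3.05), 0.006, (-0.002, 0.014)),
        "belief": SingleModelRow(0.010, (-0.016, 0.037), 1.12, (1.07, 1.18), 0.001, (-0.002, 0.004)),
        "enjoyment": SingleModelRow(0.014, (0.002, 0.026), 2.60, (2.27, 2.96), 0.013, (0.002, 0.025)),
        "pbc": SingleModelRow(0.033, (0.016, 0.050), 2.19, (2.02, 2.38), 0.026, (0.012, 0.040)),
    },
}

# Multiple mediation models.  Mediators excluded from an exposure's multiple
# model (single-model CI covered zero) have all-None rows.
MULTIPLE_MODELS = {
    "equipment": {
        "attitude": MultipleModelRow(1.33, (1.10, 1.61), 0.008, (0.002, 0.013), 6.6),
        "belief": MultipleModelRow(1.07, (1.02, 1.12), 0.003, (0.001, 0.006), 2.8),
        "enjoyment": MultipleModelRow(1.62, (1.39, 1.88), 0.016, (0.010, 0.023), 12.8),
        "pbc": MultipleModelRow(1.85, (1.69, 2.01), 0.029, (0.020, 0.038), 21.0),
    },
    "financial": {
        "attitude": MultipleModelRow(1.30, (1.07, 1.58), 0.011, (0.003, 0.020), 2.9),
        "belief": MultipleModelRow(1.07, (1.02, 1.13), 0.003, (0.000, 0.006), 0.8),
        "enjoyment": MultipleModelRow(1.50, (1.30, 1.74), 0.032, (0.020, 0.045), 8.1),
        "pbc": MultipleModelRow(1.83, (1.67, 2.00), 0.053, (0.039, 0.066), 12.5),
    },
    "logistic": {
        "attitude": MultipleModelRow(1.34, (1.11, 1.63), 0.011, (0.003, 0.018), 3.1),
        "belief": MultipleModelRow(1.08, (1.03, 1.13), 0.002, (0.000, 0.005), 0.7),
        "enjoyment": MultipleModelRow(1.53, (1.32, 1.78), 0.030, (0.018, 0.041), 8.2),
        "pbc": MultipleModelRow(1.82, (1.66, 1.99), 0.052, (0.039, 0.065), 13.5),
    },
    "emotional": {
        "attitude": MultipleModelRow(1.35, (1.12, 1.63), 0.011, (0.003, 0.018), 3.1),
        "belief": MultipleModelRow(1.07, (1.02, 1.12), 0.004, (0.000, 0.008), 1.2),
        "enjoyment": MultipleModelRow(1.59, (1.37, 1.85), 0.029, (0.017, 0.041), 8.1),
        "pbc": MultipleModelRow(1.83, (1.67, 2.00), 0.053, (0.035, 0.070), 13.9),
    },
    "reinforcement": {
        "attitude": MultipleModelRow(None, None, None, None, None),
        "belief": MultipleModelRow(None, None, None, None, None),
        "enjoyment": MultipleModelRow(1.82, (1.58, 2.09), 0.009, (0.000, 0.019), 50.3),
        "pbc": MultipleModelRow(1.90, (1.74, 2.07), 0.016, (0.002, 0.030), 63.1),
    },
    "modelling": {
        "attitude": MultipleModelRow(1.37, (1.14, 1.66), 0.002, (0.000, 0.004), 3.8),
        "belief": MultipleModelRow(1.07, (1.02, 1.13), 0.002, (0.000, 0.004), 3.8),
        "enjoyment": MultipleModelRow(1.63, (1.41, 1.89), 0.004, (0.000, 0.007), 6.2),
        "pbc": MultipleModelRow(1.85, (1.69, 2.02), 0.013, (0.007, 0.019), 19.6),
    },
    "coparticipation": {
        "attitude": MultipleModelRow(None, None, None, None, None),
        "belief": MultipleModelRow(None, None, None, None, None),
        # percentages suppressed: inconsistent mediation (direct and
        # indirect associations of opposite sign)
        "enjoyment": MultipleModelRow(1.82, (1.59, 2.09), 0.008, (0.001, 0.016), None),
        "pbc": MultipleModelRow(1.90, (1.74, 2.07), 0.021, (0.010, 0.033), None),
    },
}

#: published total mediated effect (sum over included mediators), its CI and
#: the published total percent mediated (None = suppressed)
TOTAL_MEDIATED = {
    "equipment": {"effect": 0.056, "ci": (0.045, 0.067), "percent": 33.9},
    "financial": {"effect": 0.099, "ci": (0.082, 0.116), "percent": 21.2},
    "logistic": {"effect": 0.092, "ci": (0.076, 0.109), "percent": 21.7},
    "emotional": {"effect": 0.096, "ci": (0.076, 0.117), "percent": 22.8},
    "reinforcement": {"effect": 0.026, "ci": (0.009, 0.042), "percent": 73.1},
    "modelling": {"effect": 0.021, "ci": (0.014, 0.028), "percent": 28.0},
    "coparticipation": {"effect": 0.030, "ci": (0.016, 0.043), "percent": None},
}


def included_mediators(exposure: str) -> list[str]:
    """Mediators retained in the published multiple model for ``exposure``."""
    block = MULTIPLE_MODELS[exposure]
    return [m for m in MEDIATORS if block[m].mediated is not None]
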