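"""Study orchestration: descriptives, full mediation run, reports.

``run_full_analysis`` drives the whole study on a coded (or synthetic)
cohort: complete-case assembly, sample descriptives with sex comparisons,
total/direct effect tables, single- and multiple-mediator models, and a
machine-readable JSON bundle.  Outputs are deterministic: the same config
and seed produce byte-identical JSON (no timestamps inside result files).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import simulate
from .coding import assemble_analytic_table
from .mediation import (
    DEFAULT_COVARIATES,
    DEFAULT_EXPOSURES,
    DEFAULT_MEDIATORS,
    MultilevelMediation,
)

__all__ = ["AnalysisConfig", "run_descriptives", "run_full_analysis", "render_report"]

log = logging.getLogger(__name__)

CONTINUOUS_COLUMNS = (
    "age_years",
    "equipment",
    "financial",
    "logistic",
    "emotional",
    "reinforcement",
    "modelling",
    "coparticipation",
    "attitude",
    "belief",
    "enjoyment",
    "pbc",
    "sport_hours",
)
CATEGORICAL_COLUMNS = ("parent_education", "sport_participant")


@dataclass
class AnalysisConfig:
    """Configuration for one end-to-end run.

    Either ``input_path`` (a coded cohort CSV) or ``truth_path`` (a YAML
    synthetic-truth file; empty string means the built-in default cohort)
    must be provided.
    """

    input_path: str | None = None
    truth_path: str | None = None
    exposures: tuple[str, ...] = DEFAULT_EXPOSURES
    mediators: tuple[str, ...] = DEFAULT_MEDIATORS
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    outcome: str = "sport_participant"
    alpha: float = 0.05
    percent_floor: float = 0.01
    method: str = "laplace"
    n_quad: int = 7
    max_iter: int = 200
    tol: float = 1e-8
    out_dir: str = "sportmed_out"
    rng_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        sets = [set(self.exposures), set(self.mediators), set(self.covariates)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("exposures, mediators and covariates must be disjoint")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("exposures", "mediators", "covariates"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


def run_descriptives(table: pd.DataFrame) -> pd.DataFrame:
    """Sample characteristics overall and by sex, with sex-difference tests.

    Continuous variables get means/SDs and an independent two-sample
    t-test; categorical variables get proportions and a chi-square test.
    Constant columns are kept with SD 0 and the test flagged undefined
    (NaN p-value).  Raises if either sex stratum is empty.
    """
    if "sex" not in table.columns:
        raise ValueError("descriptives require a coded 'sex' column")
    boys = table[table["sex"] == 1]
    girls = table[table["sex"] == 0]
    if len(boys) == 0 or len(girls) == 0:
        raise ValueError("a sex stratum is empty; sex-stratified descriptives undefined")

    rows = []
    for col in CONTINUOUS_COLUMNS:
        if col not in table.columns:
            continue
        x_b, x_g = boys[col].dropna(), girls[col].dropna()
        x_all = table[col].dropna()
        sd_all = float(x_all.std(ddof=1)) if len(x_all) > 1 else 0.0
        if sd_all == 0 or x_b.std(ddof=1) == 0 and x_g.std(ddof=1) == 0:
            p = np.nan  # degenerate: no variance to compare
        else:
            p = float(stats.ttest_ind(x_b, x_g, equal_var=True).pvalue)
        rows.append(
            {
                "variable": col,
                "kind": "continuous",
                "overall": float(x_all.mean()),
                "overall_sd": sd_all,
                "boys": float(x_b.mean()),
                "girls": float(x_g.mean()),
                "p_sex": p,
            }
        )
    for col in CATEGORICAL_COLUMNS:
        if col not in table.columns:
            continue
        sub = table[[col, "sex"]].dropna()
        ct = pd.crosstab(sub[col], sub["sex"])
        if ct.shape[0] < 2 or ct.shape[1] < 2:
            p = np.nan
        else:
            p = float(stats.chi2_contingency(ct.to_numpy()).pvalue)
        for level, frac in sub[col].value_counts(normalize=True).sort_index().items():
            b = float((boys[col] == level).mean())
            g = float((girls[col] == level).mean())
            rows.append(
                {
                    "variable": f"{col}={level}",
                    "kind": "proportion",
                    "overall": float(frac),
                    "overall_sd": np.nan,
                    "boys": b,
                    "girls": g,
                    "p_sex": p,
                }
            )
    return pd.DataFrame(rows)


def _load_cohort(config: AnalysisConfig) -> tuple[pd.DataFrame, dict]:
    meta = {}
    if config.input_path:
        df = pd.read_csv(config.input_path)
        meta["source"] = str(config.input_path)
    else:
        if config.truth_path:
            truth = simulate.truth_from_yaml(Path(config.truth_path).read_text())
            meta["source"] = f"synthetic:{config.truth_path}"
        else:
            truth = simulate.default_energy_truth()
            meta["source"] = "synthetic:default"
        df = simulate.generate_cohort(truth, seed=config.rng_seed)
        meta["truth_seed"] = int(config.rng_seed)
    return df, meta


def _result_bundle(model: MultilevelMediation, n: int, config: AnalysisConfig) -> dict:
    from .multilevel import wald_test

    out: dict = {"n": n, "alpha": config.alpha, "exposures": {}}
    for exposure in model.c_fits_:
        w = wald_test(model.c_fits_[exposure], exposure)
        block: dict = {
            "c_path": {
                "coef": w.estimate,
                "se": w.se,
                "OR": float(np.exp(w.estimate)),
                "ci_low_OR": float(np.exp(w.ci[0])),
                "ci_high_OR": float(np.exp(w.ci[1])),
                "p": w.p,
            },
            "single": [
                {
                    "mediator": r.mediator,
                    "a": r.a,
                    "se_a": r.se_a,
                    "b": r.b,
                    "b_OR": float(np.exp(r.b)),
                    "effect": r.effect,
                    "se": r.se,
                    "ci": list(r.ci),
                    "significant": r.significant,
                }
                for r in model.single_[exposure]
            ],
            "selected_mediators": model.selected_[exposure],
        }
        res = model.multiple_.get(exposure)
        if res is None:
            block["multiple"] = {"skipped": True}
        else:
            block["multiple"] = {
                "skipped": False,
                "mediators": res.mediators,
                "effects": res.effects,
                "effect_cis": {k: list(v) for k, v in res.effect_cis.items()},
                "total": res.total,
                "se_total": res.se_total,
                "ci_total": list(res.ci_total),
                "c_prime": res.c_prime,
                "direct_OR": res.direct_or,
                "percent": res.percent,
                "percent_total": res.percent_total,
                "classification": res.classification,
                "percent_suppressed": res.percent_suppressed,
            }
        out["exposures"][exposure] = block
    out["notices"] = model.notices_
    return out


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Execute the full study and write the report bundle to ``out_dir``.

    Returns the in-memory bundle: descriptives frame, fitted estimator,
    results dict and exclusion report.  On a stage failure, partial outputs
    already written remain on disk alongside a ``FAILED`` marker naming the
    stage.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        cohort, meta = _load_cohort(config)
        required = [
            config.outcome,
            "sex",
            *config.exposures,
            *config.mediators,
            "age_years",
            "parent_education",
        ]
        stage = "complete_cases"
        analytic, exclusions = assemble_analytic_table(cohort, required)
        log.info("complete cases: %d of %d", exclusions.n_kept, exclusions.n_input)

        stage = "descriptives"
        desc = run_descriptives(analytic)
        desc.to_csv(out_dir / "descriptives.csv", index=False)

        stage = "mediation"
        model = MultilevelMediation(
            exposures=config.exposures,
            mediators=config.mediators,
            covariates=config.covariates,
            outcome=config.outcome,
            alpha=config.alpha,
            percent_floor=config.percent_floor,
            method=config.method,
            n_quad=config.n_quad,
            max_iter=config.max_iter,
            tol=config.tol,
        ).fit(analytic)

        stage = "report"
        results = _result_bundle(model, len(analytic), config)
        model.total_direct_table().to_csv(out_dir / "total_direct.csv")
        model.single_table().to_csv(out_dir / "single_mediation.csv", index=False)
        model.multiple_table().to_csv(out_dir / "multiple_mediation.csv", index=False)
        (out_dir / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
        manifest = {
            "config": dataclasses.asdict(config),
            "n_input": exclusions.n_input,
            "n_analytic": exclusions.n_kept,
            "exclusions": exclusions.by_column,
            "source": meta,
            "notices": model.notices_,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (out_dir / "report.txt").write_text(render_report(results, desc))
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc
    return {
        "descriptives": desc,
        "model": model,
        "results": results,
        "exclusions": exclusions,
    }


def render_report(results: dict, descriptives: pd.DataFrame | None = None) -> str:
    """Plain-text rendering of the result bundle (three study-style tables)."""
    lines = []
    if descriptives is not None:
        lines += ["SAMPLE CHARACTERISTICS", "=" * 70]
        lines.append(
            descriptives.to_string(
                index=False, float_format=lambda v: f"{v:0.3f}", na_rep="-"
            )
        )
        lines.append("")
    lines += [f"TOTAL AND DIRECT EFFECTS (n={results['n']})", "=" * 70]
    for exposure, block in results["exposures"].items():
        c = block["c_path"]
        line = (
            f"{exposure:<16} total OR {c['OR']:.2f} ({c['ci_low_OR']:.2f}, "
            f"{c['ci_high_OR']:.2f})"
        )
        mult = block["multiple"]
        if not mult.get("skipped"):
            line += f"   direct OR {mult['direct_OR']:.2f}"
        lines.append(line)
    lines += ["", "MEDIATION", "=" * 70]
    for exposure, block in results["exposures"].items():
        lines.append(f"{exposure}:")
        for r in block["single"]:
            star = "*" if r["significant"] else " "
            lines.append(
                f"  single {r['mediator']:<10} a={r['a']:+.3f}  b OR={r['b_OR']:.2f}  "
                f"a*b={r['effect']:+.3f} ({r['ci'][0]:+.3f}, {r['ci'][1]:+.3f}){star}"
            )
        mult = block["multiple"]
        if mult.get("skipped"):
            lines.append("  multiple model skipped (no significant single-model mediators)")
        else:
            for m in mult["mediators"]:
                pct = (
                    "suppressed"
                    if mult["percent"] is None
                    else f"{mult['percent'][m]:.1f}%"
                )
                ci = mult["effect_cis"][m]
                lines.append(
                    f"  multiple {m:<9} a*b={mult['effects'][m]:+.3f} "
                    f"({ci[0]:+.3f}, {ci[1]:+.3f})  {pct}"
                )
            tot_pct = (
                "suppressed"
                if mult["percent_total"] is None
                else f"{mult['percent_total']:.1f}%"
            )
            lines.append(
                f"  TOTAL mediated {mult['total']:+.3f} "
                f"({mult['ci_total'][0]:+.3f}, {mult['ci_total'][1]:+.3f})  {tot_pct}  "
                f"[{mult['classification']}]"
            )
        lines.append("")
    if results.get("notices"):
        lines += ["NOTICES", "-" * 70, *results["notices"]]
    return "\n".join(lines) + "\n"
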