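"""End-to-end orchestration: simulate/ingest -> feature extraction -> model
fits -> publication-shaped outputs, with a content-addressed run manifest."""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from . import __version__
from . import io as kio
from .errors import ConfigurationError
from .features import PREDICTORS, build_feature_table
from .models import (
    ModelSpec,
    fit_mixed_model,
    fit_ols,
    likelihood_ratio_test,
    prepare_model_frame,
)
from .simulate import SimulationConfig, simulate_cohort
from .types import Scale

logger = logging.getLogger(__name__)

_OUTCOME_BY_NAME = {"hdrs17": "hdrs17_raw", "ymrs": "log_ymrs"}


class InputPaths(BaseModel):
    events: Path
    accel: Path
    assessments: Path


class PipelineConfig(BaseModel):
    """Exactly one of (inputs, simulation) drives the run."""

    inputs: InputPaths | None = None
    simulation: SimulationConfig | None = None
    gap_threshold_s: float = 5.0
    outcomes: list[str] = ["hdrs17", "ymrs"]
    model: str = "auto"  # mixed | ols | auto
    out_dir: Path = Path("keymood-run")
    seed: int | None = None  # overrides simulation.seed
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_source(self):
        if (self.inputs is None) == (self.simulation is None):
            raise ConfigurationError(
                "provide exactly one of 'inputs' (raw log paths) or 'simulation'"
            )
        if self.model not in {"mixed", "ols", "auto"}:
            raise ConfigurationError(f"unknown model choice {self.model!r}")
        unknown = set(self.outcomes) - set(_OUTCOME_BY_NAME)
        if unknown:
            raise ConfigurationError(f"unknown outcome(s) {sorted(unknown)}")
        return self


def summarize_variables(features: pd.DataFrame) -> pd.DataFrame:
    """Per-variable mean, SD, min, max, in the layout of the study's summary
    table, plus average per-subject-week observation counts where they apply."""
    rows = []
    hdrs = features[features["scale"] == Scale.HDRS17.value]
    base = hdrs if len(hdrs) else features
    for var in PREDICTORS:
        col = base[var].astype(float).dropna()
        rows.append(_summary_row(var, col))
    for scale in (Scale.HDRS17, Scale.YMRS):
        sub = features[features["scale"] == scale.value]
        if len(sub):
            rows.append(_summary_row(scale.value, sub["score"].astype(float)))
            if scale is Scale.YMRS:
                rows.append(
                    _summary_row(
                        "log_ymrs", np.log(sub["score"].astype(float) + 1.0)
                    )
                )
    counts = base["keypress_count"].astype(float)
    rows.append(_summary_row("keypress_count", counts))
    return pd.DataFrame(rows).set_index("variable")


def _summary_row(name: str, col: pd.Series) -> dict:
    col = col.dropna()
    if len(col) == 0:
        return {"variable": name, "mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan, "n": 0}
    return {
        "variable": name,
        "mean": float(col.mean()),
        "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
        "min": float(col.min()),
        "max": float(col.max()),
        "n": int(len(col)),
    }


def _fit_outcome(features: pd.DataFrame, outcome_name: str, model_choice: str) -> dict:
    """Fit one outcome; 'auto' fits mixed and falls back to OLS at the
    zero-variance boundary, reporting both information-criterion sets."""
    outcome = _OUTCOME_BY_NAME[outcome_name]
    report: dict = {"outcome": outcome_name}
    if model_choice in {"mixed", "auto"}:
        spec = ModelSpec(outcome=outcome, include_random_intercept=True)
        frame, _ = prepare_model_frame(features, spec)
        mixed = fit_mixed_model(frame, spec)
        null_spec = ModelSpec(outcome=outcome, predictors=(), include_random_intercept=True)
        null = fit_mixed_model(frame, null_spec)
        lrt = likelihood_ratio_test(null, mixed)
        report["mixed"] = mixed.to_dict()
        report["lrt_vs_null"] = {
            "chi_square": lrt.chi_square,
            "df": lrt.df,
            "pvalue": lrt.pvalue,
            "llf_null": lrt.llf_null,
            "llf_full": lrt.llf_full,
        }
        report["primary"] = "mixed"
        if model_choice == "auto" and mixed.boundary:
            logger.info(
                "%s: random-intercept variance at zero boundary; refitting OLS",
                outcome_name,
            )
            ols_spec = ModelSpec(outcome=outcome, include_random_intercept=False)
            oframe, _ = prepare_model_frame(features, ols_spec)
            report["ols"] = fit_ols(oframe, ols_spec).to_dict()
            report["primary"] = "ols"
    if model_choice == "ols":
        spec = ModelSpec(outcome=outcome, include_random_intercept=False)
        frame, _ = prepare_model_frame(features, spec)
        report["ols"] = fit_ols(frame, spec).to_dict()
        report["primary"] = "ols"
    # note: no multiple-testing correction is applied to the per-coefficient
    # tests; mirror that in downstream interpretation
    report["multiple_testing_correction"] = "none"
    return report


def _fmt(value, digits) -> str:
    return "—" if value is None or (isinstance(value, float) and np.isnan(value)) else f"{value:.{digits}f}"


def render_fit_table(report: dict) -> str:
    """Human-readable coefficient table (2-decimal estimates, CI, p)."""
    lines = [f"Outcome: {report['outcome']}  (primary model: {report['primary']})"]
    for kind in ("mixed", "ols"):
        fit = report.get(kind)
        if fit is None:
            continue
        lines.append(f"\n  {kind.upper()} — n = {fit['n_obs']}")
        lines.append(f"  {'term':<28}{'est (95% CI)':<32}{'P':>8}")
        for term in fit["names"]:
            est = _fmt(fit["params"][term], 2)
            lo = _fmt(fit["ci_low"][term], 2)
            hi = _fmt(fit["ci_high"][term], 2)
            p = fit["pvalues"][term]
            lines.append(f"  {term:<28}{est + ' (' + lo + ' to ' + hi + ')':<32}{p:>8.3f}")
        lines.append(
            "  log-likelihood {}  AIC {}  BIC {}".format(
                _fmt(fit["llf"], 3), _fmt(fit["aic"], 2), _fmt(fit["bic"], 2)
            )
        )
        if kind == "mixed":
            lines.append(
                "  marginal R2 {}  conditional R2 {}  sigma_u2 {}  sigma_e2 {}".format(
                    _fmt(fit["marginal_r2"], 3),
                    _fmt(fit["conditional_r2"], 3),
                    _fmt(fit["sigma_u2"], 4),
                    _fmt(fit["sigma_e2"], 4),
                )
            )
        else:
            lines.append(
                "  multiple R2 {}  adjusted R2 {}  RMSE {}  F({},{}) = {}".format(
                    _fmt(fit["multiple_r2"], 3),
                    _fmt(fit["adjusted_r2"], 3),
                    _fmt(fit["rmse"], 3),
                    fit["f_df"][0],
                    fit["f_df"][1],
                    _fmt(fit["f_stat"], 2),
                )
            )
    if "lrt_vs_null" in report:
        lrt = report["lrt_vs_null"]
        lines.append(
            f"\n  LRT vs intercept-only: chi2({lrt['df']}) = {lrt['chi_square']:.2f}, "
            f"P = {lrt['pvalue']:.4f}"
        )
    return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and return the manifest (also written to disk).

    Stages: load-or-simulate, feature extraction, variable summary, model
    fits. Row counts are logged at each stage so the retained-n of every fit
    is auditable; any stage failure aborts with the stage name and cause.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "keymood_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "stages": {},
        "files": {},
    }
    written: list[Path] = []

    def _write_df(df: pd.DataFrame, name: str) -> Path:
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.12g")
        written.append(path)
        return path

    stage = "ingest"
    try:
        if config.simulation is not None:
            sim_cfg = config.simulation
            if config.seed is not None:
                sim_cfg = sim_cfg.model_copy(update={"seed": config.seed})
            manifest["seed"] = sim_cfg.seed
            sim = simulate_cohort(sim_cfg)
            events, accel, assessments = sim.events, sim.accel, sim.assessments
            kio.write_event_log(events, out_dir / "events.csv")
            kio.write_accel_log(accel, out_dir / "accel.csv")
            kio.write_assessments(assessments, out_dir / "assessments.csv")
            written += [out_dir / "events.csv", out_dir / "accel.csv", out_dir / "assessments.csv"]
            truth_path = out_dir / "truth.json"
            with open(truth_path, "w") as fh:
                json.dump(
                    {
                        "random_intercepts": sim.truth.random_intercepts,
                        "betas": sim.truth.betas,
                        "intercepts": sim.truth.intercepts,
                        "latent_mood": sim.truth.latent_mood.to_dict(orient="records"),
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                    default=_json_default,
                )
            written.append(truth_path)
        else:
            events = kio.read_event_log(config.inputs.events)
            accel = kio.read_accel_log(config.inputs.accel)
            assessments = kio.read_assessments(config.inputs.assessments)
        n_kp = int(events["event_class"].isin(["REGULAR", "SPACE", "BACKSPACE"]).sum())
        manifest["stages"][stage] = {
            "events": len(events),
            "keypresses": n_kp,
            "accel_samples": len(accel),
            "assessments": len(assessments),
        }
        logger.info("ingest: %s", manifest["stages"][stage])

        stage = "features"
        features = build_feature_table(
            events, accel, assessments, gap_threshold_s=config.gap_threshold_s
        )
        _write_df(features, "features.csv")
        manifest["stages"][stage] = {"feature_rows": len(features)}

        stage = "summary"
        summary = summarize_variables(features)
        _write_df(summary.reset_index(), "summary.csv")
        manifest["stages"][stage] = {"variables": len(summary)}

        stage = "fit"
        fit_reports = {}
        for outcome_name in config.outcomes:
            report = _fit_outcome(features, outcome_name, config.model)
            fit_path = out_dir / f"fit_{outcome_name}.json"
            with open(fit_path, "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
            written.append(fit_path)
            table_path = out_dir / f"fit_{outcome_name}.txt"
            table_path.write_text(render_fit_table(report))
            written.append(table_path)
            primary = report[report["primary"]]
            fit_reports[outcome_name] = {
                "primary": report["primary"],
                "n_obs": primary["n_obs"],
                "llf": primary["llf"],
                "aic": primary["aic"],
                "bic": primary["bic"],
            }
            manifest["stages"].setdefault(stage, {})[outcome_name] = {
                "retained_n": primary["n_obs"]
            }
        manifest["fits"] = fit_reports
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for path in written:
        manifest["files"][path.name] = _sha256(path)
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    return manifest
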