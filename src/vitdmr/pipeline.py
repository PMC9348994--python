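"""End-to-end orchestration: simulate -> GRS -> observational -> MR -> PIF.

A single structured config (YAML or dict) drives every stage; all stochastic
stages carry explicit seeds, artifacts are tab-delimited text or JSON, and a
run log records package versions, seeds, filter counts and a SHA-256
manifest per artifact, so a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import instruments, linear_mr, nonlinear_mr, observational, pif, simulate

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "STAGES"]

log = logging.getLogger("vitdmr")

STAGES = ("simulate", "grs", "observational", "mr", "nlmr", "pif")


@dataclass
class PipelineConfig:
    output_dir: str = "vitdmr_out"
    cohort_path: str | None = None  # if None, the simulate stage writes one
    panel_path: str | None = None
    simulation: simulate.SimParams = field(default_factory=simulate.SimParams)
    # analysis options
    adjustment_levels: tuple[str, ...] = ("basic", "socioeconomic", "lifestyle",
                                          "sun", "illness")
    linear_outcomes: tuple[str, ...] = ("total_volume", "gray_volume", "white_volume",
                                        "hippocampal_volume", "wmh_volume")
    cox_outcomes: tuple[str, ...] = ("dementia_event", "stroke_event")
    # top categories merged relative to observational.DEFAULT_BINS: with an
    # exposure centred at 50 nmol/L (SD 20) the 125-240 category is empty
    bins: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, 100.0, 240.0)
    exposure_limits: tuple[float, float] = (10.0, 375.0)
    mr_covariates: tuple[str, ...] = ("age", "sex")
    strata_bounds: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, float("inf"))
    k_strata: int = 40
    drop_outlier_strata: bool = True
    reference: float = 50.0
    fp_degree: int | None = None
    curve_grid: tuple[float, float, float] = (15.0, 125.0, 2.5)  # lo, hi, step
    pif_threshold: float = 50.0
    n_bootstrap: int = 1000
    presso_n_sim: int = 1000
    seeds: dict = field(default_factory=lambda: {"simulate": 0, "mr": 1,
                                                 "nlmr": 2, "pif": 3})

    def __post_init__(self) -> None:
        for stage in ("simulate", "mr", "nlmr", "pif"):
            if stage not in self.seeds:
                raise ValueError(f"missing seed for stochastic stage {stage!r}")
        if self.k_strata < 3:
            raise ValueError("k_strata must be at least 3")


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Build a validated config from a YAML file plus overrides."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "simulation" in raw and isinstance(raw["simulation"], dict):
        sim = raw["simulation"]
        sim_known = {f.name for f in dataclasses.fields(simulate.SimParams)}
        bad = set(sim) - sim_known
        if bad:
            raise ValueError(f"unknown simulation keys: {sorted(bad)}")
        if "exposure_limits" in sim:
            sim["exposure_limits"] = tuple(sim["exposure_limits"])
        raw["simulation"] = simulate.SimParams(**sim)
    for key in ("adjustment_levels", "linear_outcomes", "cox_outcomes", "bins",
                "exposure_limits", "mr_covariates", "strata_bounds", "curve_grid"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _write_json(data, path: Path) -> None:
    path.write_text(json.dumps(_to_jsonable(data), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _State:
    """Lazily materialised inputs shared between stages."""

    def __init__(self, config: PipelineConfig, outdir: Path):
        self.config = config
        self.outdir = outdir
        self._panel: pd.DataFrame | None = None
        self._cohort: pd.DataFrame | None = None
        self.filter_counts: dict[str, int] = {}

    def panel(self) -> pd.DataFrame:
        if self._panel is None:
            path = self.config.panel_path or self.outdir / "panel.tsv"
            if not Path(path).exists():
                raise FileNotFoundError(
                    f"panel not found at {path}; run the simulate stage or set panel_path"
                )
            self._panel = simulate.read_panel(path)
        return self._panel

    def cohort(self) -> pd.DataFrame:
        if self._cohort is None:
            path = self.config.cohort_path or self.outdir / "cohort.tsv.gz"
            if not Path(path).exists():
                raise FileNotFoundError(
                    f"cohort not found at {path}; run the simulate stage or set cohort_path"
                )
            df = simulate.read_cohort(path)
            self._cohort = self._filter(df)
        return self._cohort

    def set(self, panel: pd.DataFrame, cohort: pd.DataFrame) -> None:
        self._panel = panel
        self._cohort = self._filter(cohort)

    def _filter(self, df: pd.DataFrame) -> pd.DataFrame:
        required = ["vitd"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"cohort is missing required columns: {missing}")
        df, n_limit = observational.exposure_outside_limits_to_missing(
            df, self.config.exposure_limits
        )
        df, n_prev = observational.exclude_prevalent(df)
        df, n_vol = observational.exclude_volume_outliers(df)
        self.filter_counts = {
            "exposure_outside_limits_set_missing": n_limit,
            "prevalent_cases_excluded": n_prev,
            "volume_outliers_excluded": n_vol,
        }
        log.info("input filters: %s", self.filter_counts)
        return df


def _stage_simulate(state: _State) -> list[Path]:
    cfg = state.config
    params = dataclasses.replace(cfg.simulation, seed=cfg.seeds["simulate"])
    panel = simulate.simulate_panel(params)
    cohort = simulate.simulate_cohort(panel, params)
    panel_path = state.outdir / "panel.tsv"
    cohort_path = state.outdir / "cohort.tsv.gz"
    simulate.write_panel(panel, panel_path)
    simulate.write_cohort(cohort, cohort_path)
    state.set(panel, cohort)
    return [panel_path, cohort_path]


def _stage_grs(state: _State) -> list[Path]:
    cohort, panel = state.cohort(), state.panel()
    grs = instruments.compute_grs(cohort, panel)
    ok = ~cohort["vitd"].isna()
    diag, resid = instruments.instrument_diagnostics(
        grs[ok], cohort.loc[ok, "vitd"].to_numpy()
    )
    path = state.outdir / "grs_diagnostics.json"
    _write_json(
        {"r2": diag.r2, "f_stat": diag.f_stat, "n": diag.n,
         "corr_residual_exposure": float(np.corrcoef(resid, cohort.loc[ok, "vitd"])[0, 1])},
        path,
    )
    return [path]


def _stage_observational(state: _State) -> list[Path]:
    cfg = state.config
    cohort = state.cohort()
    rows = []
    wanted = [(o, "linear") for o in cfg.linear_outcomes] + [
        (o, "cox") for o in cfg.cox_outcomes
    ]
    absent = [o for o, _ in wanted if o not in cohort.columns]
    if absent:
        raise ValueError(f"cohort is missing required outcome columns: {absent}")
    for outcome, family in wanted:
        for level in cfg.adjustment_levels:
            spec = observational.ModelSpec(outcome=outcome, family=family,
                                           adjustment_level=level)
            res = observational.fit_continuous(cohort, spec)
            rows.append({"outcome": outcome, "family": family, "model": level,
                         "estimate": res.estimate, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "p_trend": res.p_trend,
                         "p_nonlinear": res.p_nonlinear, "ph_p": res.ph_p,
                         "n": res.n_used})
    table = pd.DataFrame(rows)
    path = state.outdir / "observational_table2.tsv"
    table.to_csv(path, sep="\t", index=False)

    cat_rows = []
    for outcome in cfg.cox_outcomes:
        spec = observational.ModelSpec(outcome=outcome, family="cox",
                                       adjustment_level=cfg.adjustment_levels[-1])
        for name, res in observational.fit_categorical(
            cohort, spec, bins=list(cfg.bins)
        ).items():
            cat_rows.append({"outcome": outcome, "bin": name,
                             "hr": float(np.exp(res.estimate)),
                             "ci_low": float(np.exp(res.ci_low)),
                             "ci_high": float(np.exp(res.ci_high)),
                             "p": res.p_trend})
    cat_path = state.outdir / "observational_categorical.tsv"
    pd.DataFrame(cat_rows).to_csv(cat_path, sep="\t", index=False)
    return [path, cat_path]


def _two_sample_stats(state: _State, outcome: str) -> pd.DataFrame:
    """Harmonized statistics: panel weights as the independent exposure side,
    covariate-adjusted per-variant logistic slopes as the outcome side."""
    cfg = state.config
    cohort, panel = state.cohort(), state.panel()
    sub = cohort.dropna(subset=["vitd"])
    cd = observational.build_design(sub, list(cfg.mr_covariates))
    C = np.column_stack([np.ones(len(sub)), cd.to_numpy(float)])
    h = linear_mr.per_variant_associations(sub, panel, outcome, C)
    h["se_exposure"] = panel["se"].to_numpy()
    h["beta_exposure"] = panel["beta"].to_numpy()
    h["harmonization_action"] = "kept"
    return h


def _stage_mr(state: _State) -> list[Path]:
    cfg = state.config
    seed = cfg.seeds["mr"]
    results = {}
    for outcome in cfg.cox_outcomes:
        h = _two_sample_stats(state, outcome)
        per_outcome = {
            m: linear_mr.estimate(h, m, n_boot=cfg.n_bootstrap, seed=seed)
            for m in linear_mr.METHODS
        }
        presso = linear_mr.mr_presso(h, n_sim=cfg.presso_n_sim, seed=seed)
        results[outcome] = {
            "methods": per_outcome,
            "mr_presso": {
                "global_p": presso.global_p,
                "n_outliers": int(presso.outlier_flags.sum()),
                "distortion_p": presso.distortion_p,
            },
            "stratified": linear_mr.stratified_estimate(
                state.cohort().dropna(subset=["vitd"]), state.panel(),
                strata_bounds=cfg.strata_bounds, outcome=outcome,
                covariates=cfg.mr_covariates, n_boot=cfg.n_bootstrap, seed=seed,
            ),
        }
    path = state.outdir / "linear_mr.json"
    _write_json(results, path)
    return [path]


def _stage_nlmr(state: _State) -> list[Path]:
    cfg = state.config
    cohort = state.cohort().dropna(subset=["vitd"]).reset_index(drop=True)
    grs = cohort["grs"].to_numpy()
    _, resid = instruments.instrument_diagnostics(grs, cohort["vitd"].to_numpy())
    strata = nonlinear_mr.stratify(resid, cfg.k_strata)
    laces = nonlinear_mr.stratum_lace(cohort, strata,
                                      covariates=tuple(cfg.mr_covariates))
    lace_path = state.outdir / "stratum_lace.tsv"
    laces.to_csv(lace_path, sep="\t", index=False)

    curve, candidates = nonlinear_mr.fit_fp(
        laces, degree=cfg.fp_degree, drop_outliers=cfg.drop_outlier_strata,
        reference=cfg.reference,
    )
    tests = nonlinear_mr.test_nonlinearity(laces,
                                           drop_outliers=cfg.drop_outlier_strata)
    lo, hi, step = cfg.curve_grid
    grid = np.arange(lo, hi + step / 2, step)
    seed = cfg.seeds["nlmr"]
    curve_df = nonlinear_mr.effect_curve(curve, grid, seed=seed)
    curve_path = state.outdir / "effect_curve.tsv"
    curve_df.to_csv(curve_path, sep="\t", index=False)

    or25 = nonlinear_mr.or_at(curve, 25.0, seed=seed)
    model_path = state.outdir / "nlmr_model.json"
    _write_json(
        {
            "degree": curve.degree,
            "powers": curve.powers,
            "theta": curve.theta,
            "theta_cov": curve.theta_cov,
            "reference": curve.reference,
            "loglik": curve.loglik,
            "nonlinearity": tests,
            "or_25_vs_reference": {"or": or25[0], "ci_low": or25[1],
                                   "ci_high": or25[2]},
            "n_strata": int(len(laces)),
            "n_outlier_strata": int(laces["outlier_flag"].sum()),
        },
        model_path,
    )
    state._curve = curve  # cached for the pif stage
    return [lace_path, curve_path, model_path]


def _stage_pif(state: _State) -> list[Path]:
    cfg = state.config
    curve = getattr(state, "_curve", None)
    if curve is None:
        model = json.loads((state.outdir / "nlmr_model.json").read_text())
        curve = nonlinear_mr.EffectCurve(
            degree=model["degree"], powers=tuple(model["powers"]),
            theta=np.array(model["theta"]), theta_cov=np.array(model["theta_cov"]),
            reference=model["reference"],
        )
    exposures = state.cohort()["vitd"].dropna().to_numpy()
    res = pif.compute_pif(exposures, curve, threshold=cfg.pif_threshold,
                          n_bootstrap=cfg.n_bootstrap, seed=cfg.seeds["pif"])
    path = state.outdir / "pif.json"
    _write_json(res, path)
    return [path]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "grs": _stage_grs,
    "observational": _stage_observational,
    "mr": _stage_mr,
    "nlmr": _stage_nlmr,
    "pif": _stage_pif,
}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages and return the artifact manifest."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = _State(config, outdir)
    manifest: dict[str, dict] = {}
    for stage in STAGES:  # preserve canonical order
        if stage not in stages:
            continue
        log.info("running stage %s", stage)
        for path in _STAGE_FNS[stage](state):
            manifest[path.name] = {"stage": stage, "sha256": _sha256(path)}
    run_log = {
        "package_version": __version__,
        "seeds": config.seeds,
        "stages": list(stages),
        "filter_counts": state.filter_counts,
        "artifacts": manifest,
    }
    _write_json(run_log, outdir / "run_log.json")
    return run_log
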