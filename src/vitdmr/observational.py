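"""Observational arm: progressively adjusted linear and Cox models.

Linear regression relates 25(OH)D (per 10 nmol/L) to brain-volume outcomes;
Cox proportional-hazards models relate it to incident dementia and stroke.
Models are weighted by (1 - kinship coefficient), adjusted along a nested
covariate ladder (basic -> socioeconomic -> lifestyle -> sun -> illness),
and accompanied by a quadratic nonlinearity test, categorical analyses with
the 50-74.9 nmol/L group as reference, and likelihood-ratio interaction
tests.  White-matter-hyperintensity volume is log-transformed before
fitting, and Cox fits attach a Schoenfeld-residual proportional-hazards
p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError, StatisticalWarning
from lifelines.statistics import proportional_hazard_test

__all__ = [
    "ADJUSTMENT_SETS",
    "CATEGORICAL_COVARIATES",
    "DEFAULT_BINS",
    "ModelSpec",
    "AssocResult",
    "fit_continuous",
    "fit_categorical",
    "test_interaction",
    "exposure_outside_limits_to_missing",
    "exclude_volume_outliers",
    "exclude_prevalent",
]

#: Nested adjustment ladder; each level is a superset of the previous one.
#: Names refer to synthetic-cohort columns and are meant to be overridden
#: from config when analysing other tables.
ADJUSTMENT_SETS: dict[str, list[str]] = {
    "basic": ["age", "sex", "center", "ethnicity", "season_month"],
    "socioeconomic": ["age", "sex", "center", "ethnicity", "season_month", "education"],
    "lifestyle": ["age", "sex", "center", "ethnicity", "season_month", "education", "bmi"],
    "sun": ["age", "sex", "center", "ethnicity", "season_month", "education", "bmi",
            "outdoor_time"],
    "illness": ["age", "sex", "center", "ethnicity", "season_month", "education", "bmi",
                "outdoor_time", "longstanding_illness"],
}

CATEGORICAL_COVARIATES = {"center", "ethnicity", "education", "season_month"}

#: 25(OH)D analysis categories (nmol/L), left-closed; the 50-74.9 group is
#: the conventional sufficiency reference.
DEFAULT_BINS = [0.0, 25.0, 50.0, 75.0, 100.0, 125.0, 240.0]

SURVIVAL_COLUMNS = {
    "dementia_event": ("dementia_time", "dementia_event"),
    "stroke_event": ("stroke_time", "stroke_event"),
}

#: Outcomes fit on the log scale due to skewness.
LOG_OUTCOMES = {"wmh_volume"}


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    family: str = "linear"  # {"linear", "cox"}
    adjustment_level: str = "basic"
    exposure_form: str = "per_10nmol"  # {"per_10nmol", "categorical", "quadratic"}
    weights: bool = True
    exposure: str = "vitd"
    covariates: tuple[str, ...] | None = None  # overrides the ladder if given

    def __post_init__(self) -> None:
        if self.family not in {"linear", "cox"}:
            raise ValueError(f"unknown family {self.family!r}")
        if self.covariates is None and self.adjustment_level not in ADJUSTMENT_SETS:
            raise ValueError(f"unknown adjustment level {self.adjustment_level!r}")

    def covariate_list(self) -> list[str]:
        if self.covariates is not None:
            return list(self.covariates)
        return ADJUSTMENT_SETS[self.adjustment_level]


@dataclass
class AssocResult:
    estimate: float
    ci_low: float
    ci_high: float
    p_trend: float
    p_nonlinear: float | None
    n_used: int
    ph_p: float | None = None  # Schoenfeld proportional-hazards p (Cox only)


def build_design(
    df: pd.DataFrame,
    columns: list[str],
    categorical: set[str] = CATEGORICAL_COVARIATES,
) -> pd.DataFrame:
    """Numeric design frame: dummies (first level dropped) for categoricals."""
    parts = []
    for col in columns:
        if col in categorical or df[col].dtype == object:
            d = pd.get_dummies(df[col].astype("category"), prefix=col, drop_first=True)
            parts.append(d.astype(float))
        else:
            parts.append(df[[col]].astype(float))
    if not parts:
        return pd.DataFrame(index=df.index)
    return pd.concat(parts, axis=1)


def _prepare(cohort: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, str]:
    """Complete-case frame with ``vitd10`` and the (possibly logged) outcome."""
    cols = {spec.exposure, *spec.covariate_list(), "kinship_weight"}
    outcome = spec.outcome
    if spec.family == "cox":
        if outcome not in SURVIVAL_COLUMNS:
            raise ValueError(f"no survival columns registered for outcome {outcome!r}")
        cols.update(SURVIVAL_COLUMNS[outcome])
    else:
        cols.add(outcome)
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing required columns: {sorted(missing)}")
    df = cohort[sorted(cols)].dropna().copy()
    df["vitd10"] = df[spec.exposure] / 10.0
    yname = outcome
    if spec.family == "linear" and outcome in LOG_OUTCOMES:
        if (df[outcome] <= 0).any():
            raise ValueError(f"{outcome} must be positive for log transform")
        yname = f"log_{outcome}"
        df[yname] = np.log(df[outcome])
    return df, yname


def _fit_linear(y, X, w):
    return sm.WLS(np.asarray(y, float), sm.add_constant(X.to_numpy(float)),
                  weights=w).fit()


def _cox_fit(df: pd.DataFrame, design: pd.DataFrame, spec: ModelSpec,
             weights: np.ndarray) -> tuple[CoxPHFitter, pd.DataFrame]:
    time_col, event_col = SURVIVAL_COLUMNS[spec.outcome]
    if (df[time_col] <= 0).any():
        raise ValueError("non-positive follow-up times")
    if df[event_col].sum() == 0:
        raise ValueError("no events observed for outcome")
    frame = design.copy()
    frame["__time"] = df[time_col].to_numpy()
    frame["__event"] = df[event_col].to_numpy()
    frame["__w"] = weights
    cph = CoxPHFitter()
    # kinship weights are sampling weights in (0.5, 1]; the robust sandwich
    # correction is negligible for them and an order of magnitude slower, so
    # model-based SEs are used and lifelines' non-integer-weight warning
    # silenced
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", StatisticalWarning)
        try:
            cph.fit(frame, duration_col="__time", event_col="__event",
                    weights_col="__w")
        except ConvergenceError:
            cph.fit(frame, duration_col="__time", event_col="__event",
                    weights_col="__w", fit_options={"step_size": 0.1})
    return cph, frame


def fit_continuous(cohort: pd.DataFrame, spec: ModelSpec) -> AssocResult:
    """Association per 10 nmol/L 25(OH)D, with quadratic nonlinearity test.

    Returns the kinship-weighted estimate (beta for linear outcomes, log-HR
    for Cox), its 95% CI, the trend p-value, and the p-value of an added
    quadratic exposure term.  Cox results carry a Schoenfeld-residual
    proportional-hazards p-value for the exposure.
    """
    df, yname = _prepare(cohort, spec)
    w = df["kinship_weight"].to_numpy() if spec.weights else np.ones(len(df))
    X = build_design(df, ["vitd10"] + spec.covariate_list())
    Xq = X.copy()
    # centred square: same column space as the raw quadratic (identical test
    # of curvature) but far better conditioned for the Newton solver
    Xq.insert(1, "vitd10_sq", (df["vitd10"] - df["vitd10"].mean()) ** 2)

    if spec.family == "linear":
        res = _fit_linear(df[yname], X, w)
        est, se = res.params[1], res.bse[1]
        p_trend = res.pvalues[1]
        resq = _fit_linear(df[yname], Xq, w)
        p_nonlin = resq.pvalues[2]
        ph_p = None
    else:
        cph, frame = _cox_fit(df, X, spec, w)
        est = cph.params_["vitd10"]
        se = cph.standard_errors_["vitd10"]
        p_trend = cph.summary.loc["vitd10", "p"]
        cphq, _ = _cox_fit(df, Xq, spec, w)
        p_nonlin = cphq.summary.loc["vitd10_sq", "p"]
        ph = proportional_hazard_test(cph, frame, time_transform="rank")
        ph_p = float(ph.summary.loc["vitd10", "p"].squeeze())
    return AssocResult(
        estimate=float(est),
        ci_low=float(est - 1.96 * se),
        ci_high=float(est + 1.96 * se),
        p_trend=float(p_trend),
        p_nonlinear=float(p_nonlin),
        n_used=len(df),
        ph_p=ph_p,
    )


def fit_categorical(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    bins: list[float] = DEFAULT_BINS,
    reference_value: float = 60.0,
) -> dict[str, AssocResult]:
    """Per-category association with the bin containing ``reference_value``
    (default: 50-74.9 nmol/L) as the omitted reference.

    The reference bin's estimate is exactly 0 on the model scale (HR 1).
    Bins must cover the observed exposure support and be non-empty.
    """
    df, yname = _prepare(cohort, spec)
    x = df[spec.exposure]
    if x.min() < bins[0] or x.max() > bins[-1]:
        raise ValueError("bins do not cover the exposure support")
    edges = list(bins[:-1]) + [bins[-1] + 1e-9]  # close the top edge
    cats = pd.cut(x, bins=edges, right=False, include_lowest=True)
    counts = cats.value_counts()
    empty = [str(iv) for iv in counts.index[counts == 0]]
    if empty:
        raise ValueError(f"empty exposure bins: {empty}")
    ref_interval = None
    for iv in cats.cat.categories:
        if iv.left <= reference_value < iv.right:
            ref_interval = iv
    if ref_interval is None:
        raise ValueError("reference value outside the provided bins")
    w = df["kinship_weight"].to_numpy() if spec.weights else np.ones(len(df))
    dummies = pd.get_dummies(cats).astype(float)
    labels = {iv: f"bin_{iv.left:g}_{iv.right:g}" for iv in cats.cat.categories}
    dummies.columns = [labels[iv] for iv in dummies.columns]
    ref_label = labels[ref_interval]
    design_bins = dummies.drop(columns=ref_label)
    X = pd.concat([design_bins, build_design(df, spec.covariate_list())], axis=1)

    results: dict[str, AssocResult] = {}
    if spec.family == "linear":
        res = _fit_linear(df[yname], X, w)
        for k, name in enumerate(design_bins.columns, start=1):
            est, se, p = res.params[k], res.bse[k], res.pvalues[k]
            results[name] = AssocResult(float(est), float(est - 1.96 * se),
                                        float(est + 1.96 * se), float(p), None,
                                        len(df))
    else:
        cph, _ = _cox_fit(df, X, spec, w)
        for name in design_bins.columns:
            est = float(cph.params_[name])
            se = float(cph.standard_errors_[name])
            results[name] = AssocResult(est, est - 1.96 * se, est + 1.96 * se,
                                        float(cph.summary.loc[name, "p"]), None,
                                        len(df))
    results[ref_label] = AssocResult(0.0, 0.0, 0.0, np.nan, None, len(df))
    return results


def _loglik(family: str, df, yname, X, w, spec):
    if family == "linear":
        return _fit_linear(df[yname], X, w).llf, X.shape[1]
    cph, _ = _cox_fit(df, X, spec, w)
    return cph.log_likelihood_, X.shape[1]


def test_interaction(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    modifiers: list[str],
    three_way: list[tuple[str, str]] = (),
) -> dict[str, float]:
    """Likelihood-ratio tests for exposure x modifier interactions.

    Each two-way test compares the adjusted model with and without
    exposure-by-modifier product terms; a three-way test for a modifier pair
    adds the triple product on top of all pairwise products.  Continuous
    modifiers (age, BMI) enter linearly; categorical ones as dummies.
    """
    import dataclasses

    from scipy.stats import chi2

    all_mods = list(modifiers) + [m for pair in three_way for m in pair]
    extra = [m for m in all_mods if m not in spec.covariate_list()]
    spec_ext = dataclasses.replace(
        spec, covariates=tuple(spec.covariate_list() + extra)
    )
    df, yname = _prepare(cohort, spec_ext)
    w = df["kinship_weight"].to_numpy() if spec.weights else np.ones(len(df))
    base = build_design(df, ["vitd10"] + spec.covariate_list())
    pvals: dict[str, float] = {}

    def modifier_cols(m: str) -> pd.DataFrame:
        cols = build_design(df, [m])
        if cols.shape[1] == 0 or all(cols[c].nunique() <= 1 for c in cols.columns):
            raise ValueError(f"modifier {m!r} has a single level")
        return cols

    ll0, k0 = _loglik(spec.family, df, yname, base, w, spec)
    for m in modifiers:
        mc = modifier_cols(m)
        X1 = base.copy()
        for c in mc.columns:
            if c not in X1.columns:
                X1[c] = mc[c]
            X1[f"vitd10:{c}"] = df["vitd10"].to_numpy() * mc[c].to_numpy()
        # base may lack the modifier main effect; LRT must nest, so refit the
        # null with main effects included when they were absent
        X0 = base.copy()
        for c in mc.columns:
            if c not in X0.columns:
                X0[c] = mc[c]
        llnull, knull = _loglik(spec.family, df, yname, X0, w, spec)
        llalt, kalt = _loglik(spec.family, df, yname, X1, w, spec)
        pvals[m] = float(chi2.sf(2 * (llalt - llnull), kalt - knull))
    for m1, m2 in three_way:
        c1, c2 = modifier_cols(m1), modifier_cols(m2)
        X0 = base.copy()
        v = df["vitd10"].to_numpy()
        for c in list(c1.columns) + list(c2.columns):
            src = c1 if c in c1.columns else c2
            if c not in X0.columns:
                X0[c] = src[c]
            X0[f"vitd10:{c}"] = v * src[c].to_numpy()
        for a in c1.columns:
            for b in c2.columns:
                X0[f"{a}:{b}"] = c1[a].to_numpy() * c2[b].to_numpy()
        X1 = X0.copy()
        for a in c1.columns:
            for b in c2.columns:
                X1[f"vitd10:{a}:{b}"] = v * c1[a].to_numpy() * c2[b].to_numpy()
        ll0_, k0_ = _loglik(spec.family, df, yname, X0, w, spec)
        ll1_, k1_ = _loglik(spec.family, df, yname, X1, w, spec)
        pvals[f"{m1}:{m2}"] = float(chi2.sf(2 * (ll1_ - ll0_), k1_ - k0_))
    return pvals


# ---------------------------------------------------------------------------
# pre-fit exclusion filters


def exposure_outside_limits_to_missing(
    cohort: pd.DataFrame,
    limits: tuple[float, float] = (10.0, 375.0),
    column: str = "vitd",
) -> tuple[pd.DataFrame, int]:
    """Set exposure values outside the reportable assay limits to missing.

    Returns the filtered frame and the number of values replaced.
    """
    df = cohort.copy()
    bad = (df[column] < limits[0]) | (df[column] > limits[1])
    df.loc[bad, column] = np.nan
    return df, int(bad.sum())


def exclude_volume_outliers(
    cohort: pd.DataFrame,
    columns: list[str] | None = None,
    n_sd: float = 3.0,
) -> tuple[pd.DataFrame, int]:
    """Drop rows with any brain volume more than ``n_sd`` SD from its mean."""
    if columns is None:
        columns = [c for c in ("total_volume", "gray_volume", "white_volume",
                               "hippocampal_volume") if c in cohort.columns]
    mask = pd.Series(False, index=cohort.index)
    for c in columns:
        z = (cohort[c] - cohort[c].mean()) / cohort[c].std()
        mask |= z.abs() > n_sd
    return cohort[~mask].reset_index(drop=True), int(mask.sum())


def exclude_prevalent(cohort: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop participants with a recorded history of dementia or stroke
    (columns ``dementia_prevalent``/``stroke_prevalent``, if present)."""
    mask = pd.Series(False, index=cohort.index)
    for c in ("dementia_prevalent", "stroke_prevalent"):
        if c in cohort.columns:
            mask |= cohort[c].astype(bool)
    return cohort[~mask].reset_index(drop=True), int(mask.sum())
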