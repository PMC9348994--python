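"""Two-sample and stratified linear MR estimators, implemented from formulas.

Per-variant Wald ratios (variant-outcome over variant-exposure effects) are
combined by:

* ``ivw_re`` — inverse-variance-weighted mean with multiplicative
  random-effects SE inflation max(1, sqrt(Q/(J-1)));
* ``egger`` — weighted regression of outcome betas on exposure betas with an
  intercept (the intercept tests directional pleiotropy);
* ``weighted_median`` — 50th percentile of the weight-standardised cumulative
  distribution of sorted ratios, parametric-bootstrap SE;
* ``weighted_mode`` — maximiser of a weighted Gaussian kernel density of the
  ratios (modified-Silverman bandwidth), parametric-bootstrap SE;

plus MR-PRESSO (simulation-based residual-sum-of-squares global test,
per-variant outlier flags, outlier-corrected estimate and distortion test)
and a one-sample stratified analysis that re-estimates the per-variant
associations within strata of instrument-free exposure.

Estimates are per nmol/L of 25(OH)D; :func:`or_per_10` converts to the
odds-ratio-per-10-nmol/L reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import instrument_diagnostics

__all__ = [
    "MRResult",
    "PressoResult",
    "wald_ratios",
    "estimate",
    "mr_presso",
    "stratified_estimate",
    "or_per_10",
]

METHODS = ("ivw_re", "egger", "weighted_median", "weighted_mode")


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_variants_used: int
    cochran_q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_p: np.ndarray
    outlier_flags: np.ndarray
    corrected: MRResult | None
    distortion_p: float | None
    n_sim: int


def _arrays(h: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if "harmonization_action" in h.columns:
        h = h[h["harmonization_action"].isin(["kept", "flipped"])]
    bx = h["beta_exposure"].to_numpy(float)
    sx = h["se_exposure"].to_numpy(float)
    by = h["beta_outcome"].to_numpy(float)
    sy = h["se_outcome"].to_numpy(float)
    if (sy <= 0).any() or (sx < 0).any():
        raise ValueError("standard errors must be positive")
    return bx, sx, by, sy


def wald_ratios(h: pd.DataFrame) -> pd.DataFrame:
    """Per-variant ratio estimates beta_outcome / beta_exposure with
    first-order delta-method SE se_outcome / |beta_exposure|."""
    bx, _, by, sy = _arrays(h)
    if (bx == 0).any():
        raise ValueError("zero exposure beta: Wald ratio undefined")
    return pd.DataFrame({"ratio": by / bx, "se": sy / np.abs(bx)})


def _ivw_re(r: np.ndarray, se: np.ndarray) -> tuple[float, float, float, int]:
    w = 1.0 / se**2
    est = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - est) ** 2))
    j = r.size
    se_fe = float(np.sqrt(1.0 / np.sum(w)))
    infl = max(1.0, np.sqrt(q / (j - 1))) if j > 1 else 1.0
    return est, se_fe * infl, q, j


def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r, kind="stable")
    r, w = r[order], w[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if p[0] >= 0.5:
        return float(r[0])
    if p[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(p, 0.5, side="right")) - 1
    return float(r[k] + (r[k + 1] - r[k]) * (0.5 - p[k]) / (p[k + 1] - p[k]))


def _mode_bandwidth(r: np.ndarray, phi: float) -> float:
    mad = stats.median_abs_deviation(r, scale="normal")
    s = 0.9 * min(np.std(r, ddof=1), mad if mad > 0 else np.inf) * r.size ** (-0.2)
    if not np.isfinite(s) or s <= 0:
        s = np.std(r, ddof=1) * r.size ** (-0.2) or 1e-8
    return phi * s


def _weighted_mode(r: np.ndarray, w: np.ndarray, phi: float, n_grid: int = 512) -> float:
    h = _mode_bandwidth(r, phi)
    if h == 0 or np.ptp(r) == 0:
        return float(r[0])
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, n_grid)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2) @ w
    return float(grid[np.argmax(dens)])


def _bootstrap_se(
    fn, bx, sx, by, sy, n_boot: int, seed: int
) -> float:
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb[bxb == 0] = 1e-12
        ests[b] = fn(byb / bxb, (sy / np.abs(bxb)) ** -2)
    return float(np.std(ests, ddof=1))


def estimate(
    h: pd.DataFrame,
    method: str,
    n_boot: int = 1000,
    phi: float = 1.0,
    seed: int = 0,
) -> MRResult:
    """Combine harmonized per-variant statistics with one MR estimator."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    bx, sx, by, sy = _arrays(h)
    j = bx.size
    min_j = {"egger": 3, "ivw_re": 1}.get(method, 2)
    if j < min_j:
        raise ValueError(f"too few variants ({j}) for method {method!r}")

    if method == "egger":
        # orientation: all exposure betas positive
        sign = np.where(bx < 0, -1.0, 1.0)
        bxo, byo = bx * sign, by * sign
        w = 1.0 / sy**2
        X = np.column_stack([np.ones(j), bxo])
        xtwx = X.T @ (w[:, None] * X)
        coef = np.linalg.solve(xtwx, X.T @ (w * byo))
        resid = byo - X @ coef
        sigma2 = float(np.sum(w * resid**2) / (j - 2))
        cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
        est, se = float(coef[1]), float(np.sqrt(cov[1, 1]))
        icpt, icpt_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
        p = 2 * stats.t.sf(abs(est / se), j - 2)
        icpt_p = 2 * stats.t.sf(abs(icpt / icpt_se), j - 2)
        return MRResult("egger", est, se, est - 1.96 * se, est + 1.96 * se,
                        float(p), j, egger_intercept=icpt,
                        egger_intercept_p=float(icpt_p))

    ratios = wald_ratios(h)
    r, se_r = ratios["ratio"].to_numpy(), ratios["se"].to_numpy()
    w = 1.0 / se_r**2
    if not np.any(w > 0):
        raise ValueError("all ratio weights are zero")

    if method == "ivw_re":
        est, se, q, _ = _ivw_re(r, se_r)
        q_df = j - 1
        return MRResult("ivw_re", est, se, est - 1.96 * se, est + 1.96 * se,
                        float(2 * stats.norm.sf(abs(est / se))), j,
                        cochran_q=q, q_df=q_df, q_p=float(stats.chi2.sf(q, q_df)))
    if method == "weighted_median":
        est = _weighted_median(r, w)
        se = _bootstrap_se(lambda rr, ww: _weighted_median(rr, ww),
                           bx, sx, by, sy, n_boot, seed)
    else:  # weighted_mode
        est = _weighted_mode(r, w, phi)
        se = _bootstrap_se(lambda rr, ww: _weighted_mode(rr, ww, phi),
                           bx, sx, by, sy, n_boot, seed)
    if se == 0:
        se = 1e-12
    return MRResult(method, est, se, est - 1.96 * se, est + 1.96 * se,
                    float(2 * stats.norm.sf(abs(est / se))), j)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes (no-intercept WLS), vectorised.

    Supports stacked inputs of shape (..., J)."""
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    h: pd.DataFrame,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: global pleiotropy test, outlier detection and correction.

    The observed residual sum of squares of outcome betas about their
    leave-one-out IVW predictions is compared against ``n_sim`` parametric
    draws under the no-pleiotropy null; per-variant contributions give
    Bonferroni-corrected outlier p-values, the corrected estimate is the
    random-effects IVW after removing flagged variants, and the distortion
    test compares the observed correction against removals of random variant
    subsets of the same size.
    """
    bx, sx, by, sy = _arrays(h)
    j = bx.size
    if j < 4:
        raise ValueError("MR-PRESSO requires at least 4 variants")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2

    b_loo = _loo_slopes(bx, by, w)
    rss_obs_j = w * (by - b_loo * bx) ** 2
    rss_obs = float(np.sum(rss_obs_j))

    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    by_sim = rng.normal(b_loo * bx, sy, size=(n_sim, j))
    b_loo_sim = _loo_slopes(bx_sim, by_sim, w)
    rss_sim_j = w * (by_sim - b_loo_sim * bx_sim) ** 2
    rss_sim = rss_sim_j.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    outlier_p = (rss_sim_j >= rss_obs_j).mean(axis=0)
    flags = np.minimum(outlier_p * j, 1.0) < outlier_alpha

    corrected = None
    distortion_p = None
    hk = h[h["harmonization_action"].isin(["kept", "flipped"])] \
        if "harmonization_action" in h.columns else h
    if flags.any() and (~flags).sum() >= 2:
        corrected = estimate(hk.iloc[np.where(~flags)[0]], "ivw_re")
        est_all, _, _, _ = _ivw_re(by / bx, sy / np.abs(bx))
        d_obs = (corrected.estimate - est_all) / abs(est_all) if est_all != 0 else np.inf
        n_out = int(flags.sum())
        d_null = np.empty(n_sim)
        r_all, se_all = by / bx, sy / np.abs(bx)
        for b in range(n_sim):
            drop = rng.choice(j, size=n_out, replace=False)
            keep = np.setdiff1d(np.arange(j), drop)
            est_b, _, _, _ = _ivw_re(r_all[keep], se_all[keep])
            d_null[b] = (est_b - est_all) / abs(est_all) if est_all != 0 else np.inf
        distortion_p = float(np.mean(np.abs(d_null) >= abs(d_obs)))
    return PressoResult(rss_obs, global_p, outlier_p, flags, corrected,
                        distortion_p, n_sim)


# ---------------------------------------------------------------------------
# one-sample stratified MR


def _residualizer(C: np.ndarray):
    q, _ = np.linalg.qr(C)
    return lambda v: v - q @ (q.T @ v)


def logit_slope(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """Last-column slope and SE of a logistic fit, with an L-BFGS fallback
    when Newton iterations stall (small strata, sparse events)."""
    import statsmodels.api as sm

    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    model = sm.Logit(y, X)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = model.fit(disp=0, maxiter=100)
        if not fit.mle_retvals.get("converged", True):
            fit = model.fit(disp=0, method="lbfgs", maxiter=500)
    return float(fit.params[-1]), float(fit.bse[-1])


def per_variant_associations(
    df: pd.DataFrame,
    panel: pd.DataFrame,
    outcome: str,
    covariate_design: np.ndarray | None,
    family: str = "logistic",
) -> pd.DataFrame:
    """Per-variant exposure (OLS) and outcome (logistic or Cox) associations.

    Exposure slopes use the Frisch-Waugh-Lovell residualisation so all
    variants share one covariate projection; outcome models are fit per
    variant.  Returns a harmonized-statistics frame ready for the two-sample
    estimators.
    """
    import statsmodels.api as sm

    n = len(df)
    dose_cols = [f"dosage_{v}" for v in panel["variant_id"]]
    D = df[dose_cols].to_numpy(float)
    v = df["vitd"].to_numpy(float)
    y = df[outcome].to_numpy(float)
    C = covariate_design if covariate_design is not None else np.ones((n, 1))
    resid = _residualizer(C)
    Dr = resid(D)
    vr = resid(v)
    dd = np.sum(Dr * Dr, axis=0)
    if (dd <= 0).any():
        raise ValueError("variant with zero dosage variance in stratum")
    bx = (Dr.T @ vr) / dd
    dof = n - C.shape[1] - 1
    rss = np.sum(vr * vr) - bx**2 * dd
    se_bx = np.sqrt(np.maximum(rss, 0) / dof / dd)

    by = np.empty(len(dose_cols))
    se_by = np.empty(len(dose_cols))
    if family == "logistic":
        for k in range(D.shape[1]):
            by[k], se_by[k] = logit_slope(y, np.column_stack([C, D[:, k]]))
    elif family == "cox":
        from lifelines import CoxPHFitter

        time_col = outcome.replace("_event", "_time")
        for k in range(D.shape[1]):
            frame = pd.DataFrame(np.column_stack([C[:, 1:], D[:, k]]))
            frame.columns = [f"c{i}" for i in range(C.shape[1] - 1)] + ["dosage"]
            frame["__t"] = df[time_col].to_numpy()
            frame["__e"] = y
            cph = CoxPHFitter().fit(frame, "__t", "__e")
            by[k] = cph.params_["dosage"]
            se_by[k] = cph.standard_errors_["dosage"]
    else:
        raise ValueError(f"unknown outcome family {family!r}")
    return pd.DataFrame(
        {
            "variant_id": panel["variant_id"].to_numpy(),
            "beta_exposure": bx,
            "se_exposure": se_bx,
            "beta_outcome": by,
            "se_outcome": se_by,
        }
    )


def stratified_estimate(
    cohort: pd.DataFrame,
    panel: pd.DataFrame,
    strata_bounds: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, np.inf),
    outcome: str = "dementia_event",
    covariates: tuple[str, ...] = ("age", "sex"),
    methods: tuple[str, ...] = METHODS,
    family: str = "logistic",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, dict]:
    """Linear MR estimators within strata of instrument-free 25(OH)D.

    Strata are defined on the re-centred residual of the exposure after
    removing the GRS contribution (left-closed intervals on the nmol/L
    scale).  Within each stratum the per-variant exposure and outcome
    associations are re-estimated and every requested estimator applied.
    """
    from .observational import build_design

    if len(strata_bounds) < 2:
        raise ValueError("strata_bounds must define at least one stratum")
    _, resid = instrument_diagnostics(cohort["grs"].to_numpy(), cohort["vitd"].to_numpy())
    out: dict[str, dict] = {}
    for lo, hi in zip(strata_bounds[:-1], strata_bounds[1:]):
        label = f"[{lo:g},{hi:g})"
        mask = (resid >= lo) & (resid < hi)
        sub = cohort[mask]
        if sub.empty:
            raise ValueError(f"stratum {label} is empty")
        if sub[outcome].sum() == 0:
            raise ValueError(f"stratum {label} has zero events")
        cd = build_design(sub, list(covariates))
        C = np.column_stack([np.ones(len(sub)), cd.to_numpy(float)]) \
            if cd.shape[1] else np.ones((len(sub), 1))
        h = per_variant_associations(sub, panel, outcome, C, family=family)
        res = {
            m: estimate(h, m, n_boot=n_boot, seed=seed)
            for m in methods
        }
        out[label] = {
            "n": int(mask.sum()),
            "n_events": int(sub[outcome].sum()),
            "mean_exposure": float(sub["vitd"].mean()),
            "results": res,
        }
    return out


def or_per_10(result: MRResult) -> tuple[float, float, float]:
    """Exponentiate a per-nmol/L estimate to an OR per 10 nmol/L with CI."""
    return (
        float(np.exp(10 * result.estimate)),
        float(np.exp(10 * result.ci_low)),
        float(np.exp(10 * result.ci_high)),
    )
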