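"""Nonlinear MR: instrument-free stratification, LACE, fractional polynomials.

The one-sample nonlinear analysis proceeds in four steps:

1. :func:`stratify` cuts the cohort into K equal-size strata of
   instrument-free exposure (residual of 25(OH)D on the GRS, re-centred to
   the measured scale), avoiding collider bias because the residual is
   orthogonal to the instrument.
2. :func:`stratum_lace` estimates, within each stratum, the GRS-exposure
   slope (linear model) and the GRS-outcome slope (logistic by default),
   forming the localized average causal effect LACE = beta_gy / beta_gx with
   delta-method SE — an estimate of the local derivative of the causal
   log-odds dose-response.  Strata whose GRS-exposure slope falls outside
   the 99.7% prediction band around the precision-weighted pooled slope are
   flagged as violating the constant-instrument-effect assumption.
3. :func:`fit_fp` meta-regresses the LACE estimates against mean stratum
   exposure using fractional polynomials: the causal effect function is
   h(x) = sum_d theta_d f_{p_d}(x) with f_p(x) = x^p (f_0 = ln x; repeated
   powers use the ln-augmented convention), and each stratum contributes
   LACE_k ~ h'(mean_k) with weight 1/se^2.  Degree 1 scans all 8 canonical
   powers, degree 2 all 36 pairs; degree 2 is retained only when it beats
   the best degree 1 at p < 0.05.
4. :func:`effect_curve` reconstructs OR(x) = exp(h(x) - h(reference)) with
   simulation-based confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FP_POWERS",
    "StratumLACE",
    "EffectCurve",
    "stratify",
    "stratum_lace",
    "fit_fp",
    "test_nonlinearity",
    "effect_curve",
    "or_at",
]

#: Canonical fractional-polynomial power family (0 denotes log).
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

LACE_COLUMNS = [
    "index", "n", "n_events", "mean_exposure",
    "beta_gx", "se_gx", "beta_gy", "se_gy",
    "lace", "se_lace", "outlier_flag",
]


@dataclass
class StratumLACE:
    index: int
    n: int
    n_events: int
    mean_exposure: float
    beta_gx: float
    se_gx: float
    beta_gy: float
    se_gy: float
    lace: float
    se_lace: float
    outlier_flag: bool


@dataclass
class EffectCurve:
    degree: int
    powers: tuple[float, ...]
    theta: np.ndarray
    theta_cov: np.ndarray
    reference: float = 50.0
    support: tuple[float, float] = (10.0, 240.0)
    loglik: float = np.nan

    def h_delta(self, x) -> np.ndarray:
        """h(x) - h(reference), the causal log-odds contrast."""
        x = np.asarray(x, dtype=float)
        fx = _basis(x, self.powers)
        fr = _basis(np.array([self.reference]), self.powers)
        return (fx - fr) @ self.theta


def stratify(residual_exposure: np.ndarray, k: int) -> np.ndarray:
    """Equal-size quantile strata (1..k), sizes differing by at most one.

    Ties are broken by stable input order.
    """
    r = np.asarray(residual_exposure)
    n = r.size
    if k < 3:
        raise ValueError("need at least 3 strata")
    if n < 10 * k:
        raise ValueError(f"k={k} too large for n={n} (need n >= 10k)")
    order = np.argsort(r, kind="stable")
    labels = np.empty(n, dtype=int)
    for i, chunk in enumerate(np.array_split(order, k), start=1):
        labels[chunk] = i
    return labels


def _slope_with_se(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    fit = sm.OLS(y, X).fit()
    return float(fit.params[-1]), float(fit.bse[-1])


def stratum_lace(
    cohort: pd.DataFrame,
    strata: np.ndarray,
    covariates: tuple[str, ...] = (),
    outcome: str = "dementia_event",
    exposure: str = "vitd",
    grs_col: str = "grs",
    family: str = "logistic",
    outlier_band_sd: float = 3.0,
) -> pd.DataFrame:
    """Per-stratum LACE estimates with instrument-assumption outlier flags."""
    from .observational import build_design

    rows = []
    for idx in np.unique(strata):
        sub = cohort[strata == idx]
        g = sub[grs_col].to_numpy(float)
        if np.var(g) == 0:
            raise ValueError(f"stratum {idx} has zero GRS variance")
        events = int(sub[outcome].sum())
        if events == 0:
            raise ValueError(f"stratum {idx} has zero events")
        cd = build_design(sub, list(covariates))
        X = np.column_stack([np.ones(len(sub)), cd.to_numpy(float), g]) \
            if cd.shape[1] else np.column_stack([np.ones(len(sub)), g])
        bx, se_x = _slope_with_se(sub[exposure].to_numpy(float), X)
        if family == "logistic":
            from .linear_mr import logit_slope

            by, se_y = logit_slope(sub[outcome].to_numpy(float), X)
        elif family == "cox":
            from lifelines import CoxPHFitter

            frame = pd.DataFrame(X[:, 1:], columns=[f"x{i}" for i in range(X.shape[1] - 1)])
            frame["__t"] = sub[outcome.replace("_event", "_time")].to_numpy()
            frame["__e"] = sub[outcome].to_numpy()
            cph = CoxPHFitter().fit(frame, "__t", "__e")
            by = float(cph.params_[f"x{X.shape[1] - 2}"])
            se_y = float(cph.standard_errors_[f"x{X.shape[1] - 2}"])
        else:
            raise ValueError(f"unknown outcome family {family!r}")
        if bx == 0:
            raise ValueError(f"stratum {idx} has zero GRS-exposure slope")
        rows.append(
            StratumLACE(
                index=int(idx), n=len(sub), n_events=events,
                mean_exposure=float(sub[exposure].mean()),
                beta_gx=bx, se_gx=se_x, beta_gy=by, se_gy=se_y,
                lace=by / bx, se_lace=se_y / abs(bx), outlier_flag=False,
            )
        )
    df = pd.DataFrame([vars(r) for r in rows]).sort_values("mean_exposure")
    df = df.reset_index(drop=True)
    # flag strata whose GRS-exposure slope departs from the pooled slope
    w = 1.0 / df["se_gx"] ** 2
    pooled = float(np.sum(w * df["beta_gx"]) / np.sum(w))
    df["outlier_flag"] = (
        np.abs(df["beta_gx"] - pooled) > outlier_band_sd * df["se_gx"]
    )
    return df[LACE_COLUMNS]


# ---------------------------------------------------------------------------
# fractional-polynomial basis (values and derivatives)


def _f(x: np.ndarray, p: float) -> np.ndarray:
    return np.log(x) if p == 0 else x**p


def _fprime(x: np.ndarray, p: float) -> np.ndarray:
    return 1.0 / x if p == 0 else p * x ** (p - 1)


def _g(x: np.ndarray, p: float) -> np.ndarray:
    """ln-augmented second basis function for a repeated power."""
    return np.log(x) ** 2 if p == 0 else x**p * np.log(x)


def _gprime(x: np.ndarray, p: float) -> np.ndarray:
    return 2 * np.log(x) / x if p == 0 else x ** (p - 1) * (p * np.log(x) + 1)


def _columns(x: np.ndarray, powers: tuple[float, ...], deriv: bool) -> np.ndarray:
    cols = []
    seen: dict[float, int] = {}
    for p in powers:
        rep = seen.get(p, 0)
        if rep == 0:
            cols.append(_fprime(x, p) if deriv else _f(x, p))
        elif rep == 1:
            cols.append(_gprime(x, p) if deriv else _g(x, p))
        else:
            raise ValueError("powers repeated more than twice are not supported")
        seen[p] = rep + 1
    return np.column_stack(cols)


def _basis(x: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    return _columns(x, powers, deriv=False)


def _basis_deriv(x: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    return _columns(x, powers, deriv=True)


def _wls_fp(
    m: np.ndarray, lace: np.ndarray, w: np.ndarray, powers: tuple[float, ...]
) -> tuple[np.ndarray, np.ndarray, float]:
    X = _basis_deriv(m, powers)
    xtwx = X.T @ (w[:, None] * X)
    theta = np.linalg.solve(xtwx, X.T @ (w * lace))
    cov = np.linalg.inv(xtwx)
    resid = lace - X @ theta
    ll = float(-0.5 * np.sum(w * resid**2) - 0.5 * np.sum(np.log(2 * np.pi / w)))
    return theta, cov, ll


def _unflagged(laces: pd.DataFrame, drop_outliers: bool) -> pd.DataFrame:
    if drop_outliers and "outlier_flag" in laces.columns:
        return laces[~laces["outlier_flag"].astype(bool)]
    return laces


def fit_fp(
    laces: pd.DataFrame,
    degree: int | None = None,
    powers_set: tuple[float, ...] = FP_POWERS,
    drop_outliers: bool = True,
    alpha_degree: float = 0.05,
    reference: float = 50.0,
    support: tuple[float, float] = (10.0, 240.0),
) -> tuple[EffectCurve, pd.DataFrame]:
    """Weighted fractional-polynomial meta-regression of LACE on exposure.

    Returns the selected :class:`EffectCurve` and a table of all candidate
    models with their weighted Gaussian log-likelihoods.  ``degree=None``
    selects degree 2 over the best degree 1 only at p < ``alpha_degree``
    (chi-square, 2 df).
    """
    use = _unflagged(laces, drop_outliers)
    m = use["mean_exposure"].to_numpy(float)
    if (m <= 0).any():
        raise ValueError("stratum mean exposures must be positive for the FP basis")
    lace = use["lace"].to_numpy(float)
    w = 1.0 / use["se_lace"].to_numpy(float) ** 2
    max_degree = 2 if degree is None else degree
    if len(use) < max_degree + 2:
        raise ValueError(
            f"need at least degree+2={max_degree + 2} unflagged strata, have {len(use)}"
        )
    candidates = []
    fits: dict[tuple[float, ...], tuple[np.ndarray, np.ndarray, float]] = {}
    for p in powers_set:
        fits[(p,)] = _wls_fp(m, lace, w, (p,))
        candidates.append({"degree": 1, "powers": (p,), "loglik": fits[(p,)][2]})
    if max_degree >= 2:
        for pq in combinations_with_replacement(powers_set, 2):
            fits[pq] = _wls_fp(m, lace, w, pq)
            candidates.append({"degree": 2, "powers": pq, "loglik": fits[pq][2]})
    cand = pd.DataFrame(candidates)

    best1 = cand[cand["degree"] == 1].sort_values("loglik").iloc[-1]
    choice = tuple(best1["powers"])
    if max_degree >= 2:
        best2 = cand[cand["degree"] == 2].sort_values("loglik").iloc[-1]
        if degree == 2:
            choice = tuple(best2["powers"])
        elif degree is None:
            lr = 2 * (best2["loglik"] - best1["loglik"])
            if stats.chi2.sf(lr, 2) < alpha_degree:
                choice = tuple(best2["powers"])
    theta, cov, ll = fits[choice]
    curve = EffectCurve(
        degree=len(choice), powers=choice, theta=theta, theta_cov=cov,
        reference=reference, support=support, loglik=ll,
    )
    return curve, cand


def test_nonlinearity(
    laces: pd.DataFrame,
    powers_set: tuple[float, ...] = FP_POWERS,
    drop_outliers: bool = True,
) -> dict[str, float]:
    """Nonlinearity and heterogeneity tests on the LACE profile.

    * ``p_fp`` — best degree-1 fractional polynomial against the linear
      (power-1, constant-derivative) model, chi-square with 1 df;
    * ``p_quadratic`` — Wald p of the slope in the precision-weighted
      meta-regression of LACE on mean exposure (a linear trend in the
      derivative corresponds to a quadratic effect function);
    * ``p_q`` — Cochran Q heterogeneity of the LACE estimates about their
      precision-weighted pooled value.
    """
    use = _unflagged(laces, drop_outliers)
    if len(use) < 4:
        raise ValueError("need at least 4 unflagged strata")
    m = use["mean_exposure"].to_numpy(float)
    lace = use["lace"].to_numpy(float)
    w = 1.0 / use["se_lace"].to_numpy(float) ** 2

    ll_lin = _wls_fp(m, lace, w, (1.0,))[2]
    ll_best = max(_wls_fp(m, lace, w, (p,))[2] for p in powers_set)
    p_fp = float(stats.chi2.sf(2 * (ll_best - ll_lin), 1))

    X = np.column_stack([np.ones_like(m), m])
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * lace))
    se_b = float(np.sqrt(np.linalg.inv(xtwx)[1, 1]))
    p_quad = float(2 * stats.norm.sf(abs(beta[1] / se_b)))

    pooled = float(np.sum(w * lace) / np.sum(w))
    q = float(np.sum(w * (lace - pooled) ** 2))
    p_q = float(stats.chi2.sf(q, len(use) - 1))
    return {"p_fp": p_fp, "p_quadratic": p_quad, "p_q": p_q}


def effect_curve(
    curve: EffectCurve,
    x_grid: np.ndarray,
    reference: float | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """OR(x) = exp(h(x) - h(reference)) on a grid, with simulation CI bands.

    Confidence bands come from ``n_draws`` multivariate-normal draws of the
    coefficient vector (percentile method), so they are exactly 1 at the
    reference point.
    """
    x = np.asarray(x_grid, dtype=float)
    lo, hi = curve.support
    if (x < lo).any() or (x > hi).any():
        raise ValueError(f"grid values outside curve support [{lo}, {hi}]")
    ref = curve.reference if reference is None else reference
    work = EffectCurve(curve.degree, curve.powers, curve.theta, curve.theta_cov,
                       reference=ref, support=curve.support)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(curve.theta, curve.theta_cov, size=n_draws)
    fx = _basis(x, curve.powers) - _basis(np.array([ref]), curve.powers)
    h_draws = fx @ draws.T  # (len(x), n_draws)
    point = np.exp(work.h_delta(x))
    ci = np.exp(np.quantile(h_draws, [alpha / 2, 1 - alpha / 2], axis=1))
    return pd.DataFrame({"x": x, "or": point, "ci_low": ci[0], "ci_high": ci[1]})


def or_at(
    curve: EffectCurve,
    x: float,
    reference: float | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """OR with CI for one exposure value against the reference."""
    df = effect_curve(curve, np.array([x]), reference=reference,
                      n_draws=n_draws, seed=seed)
    return float(df["or"][0]), float(df["ci_low"][0]), float(df["ci_high"][0])
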