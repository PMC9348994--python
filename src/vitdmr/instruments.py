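"""Genetic-instrument handling: selection, harmonization, GRS, diagnostics.

Variant panels and GWAS summary statistics are plain pandas DataFrames read
from tab-delimited text with the header names

    variant_id, effect_allele, other_allele, eaf, beta, se, pval

(plus an optional ``block`` column carrying functional-block labels).
The weighted genetic risk score (GRS) built here serves as the single
instrument for 25(OH)D throughout the MR modules; the "instrument-free"
exposure is the residual from regressing measured 25(OH)D on the GRS,
re-centered to the measured nmol/L scale so that deficiency thresholds
(25/50 nmol/L) keep their meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SUMMARY_COLUMNS",
    "InstrumentDiagnostics",
    "read_summary_stats",
    "select_instruments",
    "harmonize",
    "compute_grs",
    "instrument_diagnostics",
    "leave_block_out",
]

SUMMARY_COLUMNS = ["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset("AT"), frozenset("CG")}


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """Strength of the GRS as an instrument for the exposure."""

    r2: float
    f_stat: float
    n: int


def read_summary_stats(path) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics table, validating the header."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistics file {path} missing columns: {missing}")
    return df


def select_instruments(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    maf_min: float = 0.05,
    p_replication: float = 0.05,
) -> pd.DataFrame:
    """Select instruments replicated in an independent GWAS.

    Keeps variants present in both tables with MAF > ``maf_min``, replication
    p < ``p_replication`` and directionally consistent effects; the returned
    panel carries the replication (discovery-independent) betas as weights
    and the discovery-side allele frequency, so weights from an external
    consortium can be applied to cohort genotypes.
    """
    merged = discovery.merge(
        replication, on="variant_id", suffixes=("_disc", "_repl"), how="inner"
    )
    if merged.empty:
        raise ValueError("no variant IDs shared between discovery and replication tables")
    maf = np.minimum(merged["eaf_disc"], 1 - merged["eaf_disc"])
    keep = (
        (maf > maf_min)
        & (merged["pval_repl"] < p_replication)
        & (np.sign(merged["beta_disc"]) == np.sign(merged["beta_repl"]))
        & (merged["beta_disc"] != 0)
    )
    sel = merged[keep]
    panel = pd.DataFrame(
        {
            "variant_id": sel["variant_id"],
            "effect_allele": sel["effect_allele_disc"],
            "other_allele": sel["other_allele_disc"],
            "eaf": sel["eaf_disc"],
            "beta": sel["beta_repl"],
            "se": sel["se_repl"],
            "pval": sel["pval_repl"],
        }
    )
    panel["block"] = sel["block_disc"] if "block_disc" in sel else (
        sel["block"] if "block" in sel else "unassigned"
    )
    return panel.reset_index(drop=True)


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMIC


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_window: tuple[float, float] = (0.40, 0.60),
) -> pd.DataFrame:
    """Align exposure and outcome summary statistics on the effect allele.

    Classification per variant (recorded in ``harmonization_action``):

    * ``kept`` — same orientation (directly or after strand complement);
    * ``flipped`` — alleles swapped: outcome beta negated, EAF reflected;
    * ``dropped_palindromic`` — A/T or C/G variant with exposure EAF inside
      ``palindromic_window`` (strand is unresolvable near 50% frequency);
      outside the window the minor/major-allele agreement of the two EAFs
      decides the orientation;
    * ``dropped_mismatch`` — irreconcilable allele pairs.

    The returned frame contains all intersected variants with aligned
    ``beta_outcome``/``eaf_outcome``; rows with a ``dropped_*`` action carry
    their original (unaligned) outcome values and are excluded by
    downstream estimators.
    """
    for side, df in (("exposure", exposure), ("outcome", outcome)):
        for col in ("effect_allele", "other_allele"):
            if col not in df.columns:
                raise ValueError(f"{side} table missing allele column {col!r}")
    m = exposure.merge(outcome, on="variant_id", suffixes=("_exposure", "_outcome"))
    actions, betas, eafs = [], [], []
    for row in m.itertuples(index=False):
        ea_x = str(row.effect_allele_exposure).upper()
        oa_x = str(row.other_allele_exposure).upper()
        ea_y = str(row.effect_allele_outcome).upper()
        oa_y = str(row.other_allele_outcome).upper()
        beta_y, eaf_y = row.beta_outcome, row.eaf_outcome
        if _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                actions.append("dropped_mismatch")
                betas.append(beta_y)
                eafs.append(eaf_y)
                continue
            lo, hi = palindromic_window
            if lo <= row.eaf_exposure <= hi:
                actions.append("dropped_palindromic")
                betas.append(beta_y)
                eafs.append(eaf_y)
                continue
            # strand unresolvable from alleles alone: orient by minor/major
            # agreement of the two allele frequencies
            if ea_y != ea_x:  # nominal swap first
                beta_y, eaf_y = -beta_y, 1 - eaf_y
            if (row.eaf_exposure < 0.5) != (eaf_y < 0.5):  # implied strand flip
                beta_y, eaf_y = -beta_y, 1 - eaf_y
            actions.append("kept" if beta_y == row.beta_outcome else "flipped")
            betas.append(beta_y)
            eafs.append(eaf_y)
            continue
        ca_y, co_y = _COMPLEMENT.get(ea_y, "?"), _COMPLEMENT.get(oa_y, "?")
        if (ea_y, oa_y) == (ea_x, oa_x) or (ca_y, co_y) == (ea_x, oa_x):
            actions.append("kept")
            betas.append(beta_y)
            eafs.append(eaf_y)
        elif (oa_y, ea_y) == (ea_x, oa_x) or (co_y, ca_y) == (ea_x, oa_x):
            actions.append("flipped")
            betas.append(-beta_y)
            eafs.append(1 - eaf_y)
        else:
            actions.append("dropped_mismatch")
            betas.append(beta_y)
            eafs.append(eaf_y)
    out = pd.DataFrame(
        {
            "variant_id": m["variant_id"],
            "effect_allele": m["effect_allele_exposure"],
            "other_allele": m["other_allele_exposure"],
            "beta_exposure": m["beta_exposure"],
            "se_exposure": m["se_exposure"],
            "eaf_exposure": m["eaf_exposure"],
            "beta_outcome": betas,
            "se_outcome": m["se_outcome"],
            "eaf_outcome": eafs,
            "harmonization_action": actions,
        }
    )
    return out


def kept(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows usable for estimation (action ``kept`` or ``flipped``)."""
    return harmonized[
        harmonized["harmonization_action"].isin(["kept", "flipped"])
    ].reset_index(drop=True)


def compute_grs(dosages, panel: pd.DataFrame) -> np.ndarray:
    """Weighted GRS: score_i = sum_j dosage_ij * weight_j.

    ``dosages`` is an (n, J) array or DataFrame whose columns follow the
    panel order (DataFrame columns named ``dosage_<variant_id>`` or
    ``<variant_id>`` are reordered to match).  Missing dosages are imputed
    as 2*eaf, preserving the score expectation.
    """
    weights = panel["beta"].to_numpy(dtype=float)
    if isinstance(dosages, pd.DataFrame):
        cols = []
        for vid in panel["variant_id"]:
            if f"dosage_{vid}" in dosages.columns:
                cols.append(f"dosage_{vid}")
            elif vid in dosages.columns:
                cols.append(vid)
            else:
                raise ValueError(f"dosage column for variant {vid!r} not found")
        mat = dosages[cols].to_numpy(dtype=float)
    else:
        mat = np.asarray(dosages, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != len(panel):
            raise ValueError(
                f"dosage matrix has {mat.shape[1] if mat.ndim == 2 else '?'} columns, "
                f"panel has {len(panel)} variants"
            )
    if np.isnan(mat).any():
        fill = 2 * panel["eaf"].to_numpy(dtype=float)
        idx = np.where(np.isnan(mat))
        mat = mat.copy()
        mat[idx] = fill[idx[1]]
    return mat @ weights


def instrument_diagnostics(
    grs: np.ndarray, vitd: np.ndarray
) -> tuple[InstrumentDiagnostics, np.ndarray]:
    """OLS of exposure on GRS: variance explained, F-statistic, residuals.

    F = r2 (n-2) / (1 - r2), the exact F of the simple regression.  The
    residuals are re-centered by adding back the sample mean of the exposure
    so that stratification thresholds stay on the measured nmol/L scale.
    """
    grs = np.asarray(grs, dtype=float)
    vitd = np.asarray(vitd, dtype=float)
    if grs.shape != vitd.shape:
        raise ValueError("grs and exposure must have equal length")
    n = grs.shape[0]
    if n <= 2:
        raise ValueError("need more than 2 observations")
    gc = grs - grs.mean()
    denom = float(gc @ gc)
    if denom == 0.0:
        raise ValueError("GRS has zero variance")
    vc = vitd - vitd.mean()
    slope = float(gc @ vc) / denom
    resid = vc - slope * gc
    ss_tot = float(vc @ vc)
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    f = r2 * (n - 2) / (1 - r2) if r2 < 1 else np.inf
    return InstrumentDiagnostics(r2=r2, f_stat=f, n=n), resid + vitd.mean()


def leave_block_out(
    panel: pd.DataFrame,
    block: str | None = None,
    variant_id: str | None = None,
) -> pd.DataFrame:
    """Panel with one functional block (or one variant) excluded.

    A block label with no members (including ``block=None``) returns the
    panel unchanged; excluding everything raises.  Single-variant exclusion
    via ``variant_id`` supports leave-one-out analyses and is strict about
    unknown identifiers.
    """
    if variant_id is not None and variant_id not in set(panel["variant_id"]):
        raise ValueError(f"variant {variant_id!r} not present in panel")
    keep = pd.Series(True, index=panel.index)
    if block is not None:
        keep &= panel["block"] != block
    if variant_id is not None:
        keep &= panel["variant_id"] != variant_id
    out = panel[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("exclusion would leave zero variants in the panel")
    return out
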