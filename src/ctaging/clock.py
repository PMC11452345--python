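"""Transcriptomic age estimation and acceleration testing.

A fixed gene panel with signed weights (an externally trained brain-age
predictor; synthetic panels are used in tests) is scored as a weighted sum
of normalized (log-CPM) full-pseudobulk expression.  The raw score is
rescaled to years by an ordinary least-squares calibration against
chronological age; *age acceleration* is the residual of calibrated
transcriptomic age after regressing out chronological age and library
batch (the strongest technical covariate); and the group test asks whether
disease status predicts that acceleration, controlling for sex, pH, RIN,
PMI and the hidden-confounder PC1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import design_matrix, log_cpm, tmm_norm_factors
from .io import PseudobulkAssay

__all__ = [
    "ClockPanel",
    "ClockResult",
    "read_panel",
    "raw_clock_score",
    "calibrate_clock",
    "age_acceleration",
    "test_group_acceleration",
    "run_clock",
]


@dataclass
class ClockPanel:
    """Gene panel with signed expression weights."""

    weights: pd.Series  # index gene_id, values signed weights
    provenance: str = ""

    def __post_init__(self) -> None:
        self.weights = pd.Series(self.weights, dtype=float)
        if not np.isfinite(self.weights.to_numpy()).all():
            raise ValueError("panel weights must be finite")

    @property
    def n_panel(self) -> int:
        return len(self.weights)


@dataclass
class ClockResult:
    """Per-donor scores, calibrated ages, acceleration and the group test."""

    raw_score: pd.Series
    calibrated_age: pd.Series
    acceleration: pd.Series
    slope: float
    intercept: float
    age_correlation_r: float
    coverage: tuple[int, int]  # (matched, panel size)
    group_test: pd.DataFrame | None = None


def read_panel(path: str | Path, provenance: str = "") -> ClockPanel:
    """Read a panel TSV with columns ``gene_id`` and ``weight``."""
    df = pd.read_csv(path, sep="\t")
    return ClockPanel(weights=pd.Series(df["weight"].to_numpy(), index=df["gene_id"]), provenance=provenance)


def raw_clock_score(expr: pd.DataFrame, panel: ClockPanel) -> tuple[pd.Series, tuple[int, int]]:
    """Weighted panel score per donor: sum of weight x expression.

    ``expr`` is a genes x donors normalized matrix.  Panel genes absent from
    the matrix are dropped (never imputed) and reported via the coverage
    tuple ``(n_matched, n_panel)``; zero matched genes is an error.
    """
    matched = panel.weights.index.intersection(expr.index)
    if len(matched) == 0:
        raise ValueError("no panel gene matches the expression matrix")
    w = panel.weights[matched]
    score = expr.loc[matched].T @ w
    return pd.Series(score, index=expr.columns, name="raw_score"), (len(matched), panel.n_panel)


def calibrate_clock(
    raw: pd.Series, ages: np.ndarray, mode: str = "invert"
) -> tuple[float, float, pd.Series]:
    """Rescale the raw panel score to years.

    ``mode='invert'`` (default) regresses raw score on chronological age and
    inverts the fit: ``calibrated = (raw - intercept)/slope``.  The
    alternative ``mode='predict'`` regresses chronological age on the raw
    score and uses the fitted values directly; both readings produce
    identical acceleration test statistics up to the affine rescaling.
    """
    raw = pd.Series(raw, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(raw) < 3:
        raise ValueError("need at least 3 donors to calibrate")
    if np.ptp(raw.to_numpy()) == 0:
        raise ValueError("raw scores are constant; the panel is uninformative")
    if mode == "invert":
        slope, intercept = np.polyfit(ages, raw.to_numpy(), 1)
        if slope == 0:
            raise ValueError("zero calibration slope; the panel is uninformative about age")
        calibrated = (raw - intercept) / slope
    elif mode == "predict":
        slope, intercept = np.polyfit(raw.to_numpy(), ages, 1)
        calibrated = raw * slope + intercept
    else:
        raise ValueError("mode must be 'invert' or 'predict'")
    return float(slope), float(intercept), calibrated.rename("calibrated_age")


def age_acceleration(
    calibrated: pd.Series, ages: np.ndarray, batches: pd.Series | None = None
) -> pd.Series:
    """Residual transcriptomic age after chronological age and batch.

    Least squares of calibrated age on chronological age plus library-batch
    indicators; the residual, in years, is the donor's age acceleration.
    """
    calibrated = pd.Series(calibrated, dtype=float)
    df = pd.DataFrame({"donor_id": calibrated.index, "age": np.asarray(ages, float)})
    terms = ["age"]
    if batches is not None:
        df["lib_batch"] = np.asarray(batches).astype(str)
        if df["lib_batch"].nunique() > 1:
            terms.append("lib_batch")
    X, _ = design_matrix(df, terms)
    Xv = X.to_numpy(float)
    beta, *_ = np.linalg.lstsq(Xv, calibrated.to_numpy(), rcond=None)
    resid = calibrated.to_numpy() - Xv @ beta
    return pd.Series(resid, index=calibrated.index, name="acceleration")


def test_group_acceleration(
    residuals: pd.Series,
    donors: pd.DataFrame,
    covariates: list | None = None,
) -> pd.DataFrame:
    """Regression of age-acceleration residuals on disease status + covariates.

    Default covariates are sex, pH, RIN, PMI and PC1 (those present in the
    donor table).  Returns one row per coefficient with estimate (years for
    the disease term), standard error, t and two-sided p.
    """
    default = ["disease_status", "sex", "pH", "RIN", "PMI", "PC1"]
    terms = covariates or [t for t in default if t in donors.columns]
    if "disease_status" not in terms:
        raise ValueError("the group test requires disease_status in the design")
    if donors["disease_status"].nunique() < 2:
        raise ValueError("disease_status is constant; the group test is undefined")
    X, _ = design_matrix(donors, terms)
    Xv = X.to_numpy(float)
    y = pd.Series(residuals, dtype=float).to_numpy()
    dof = len(y) - Xv.shape[1]
    if dof < 1:
        raise ValueError("too few donors for the group-test design")
    beta, *_ = np.linalg.lstsq(Xv, y, rcond=None)
    resid = y - Xv @ beta
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(Xv.T @ Xv)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame(
        {"term": X.columns, "estimate": beta, "std_error": se, "t_statistic": t, "p_value": p}
    )


def run_clock(
    assay: PseudobulkAssay,
    panel: ClockPanel,
    mode: str = "invert",
    group_test: bool = True,
) -> ClockResult:
    """Full clock procedure on a (viz-filtered) full-pseudobulk assay.

    Normalizes counts (TMM factors + log-CPM), scores the panel, calibrates
    to years, computes batch-adjusted acceleration residuals, and (when the
    donor table permits) runs the covariate-adjusted disease group test.
    """
    factors = tmm_norm_factors(assay.counts)
    expr = pd.DataFrame(log_cpm(assay.counts, factors), index=assay.counts.index, columns=assay.counts.columns)
    raw, coverage = raw_clock_score(expr, panel)
    ages = assay.donors["age"].to_numpy(float)
    slope, intercept, calibrated = calibrate_clock(raw, ages, mode=mode)
    r = float(stats.pearsonr(calibrated.to_numpy(), ages)[0])
    accel = age_acceleration(calibrated, ages, assay.donors.get("lib_batch"))
    gt = None
    if group_test and "disease_status" in assay.donors.columns and assay.donors["disease_status"].nunique() > 1:
        gt = test_group_acceleration(accel, assay.donors)
    return ClockResult(
        raw_score=raw,
        calibrated_age=calibrated,
        acceleration=accel,
        slope=slope,
        intercept=intercept,
        age_correlation_r=r,
        coverage=coverage,
        group_test=gt,
    )
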