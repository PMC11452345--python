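"""Data-driven covariate selection for the pseudobulk aging model.

Donor covariates are screened against principal components of the (stringently
filtered) full-pseudobulk expression matrix: continuous covariates by Pearson
correlation with each PC, categorical covariates by one-way ANOVA of PC scores
across levels.  A hidden-confounder component is then derived as PC1 of the
expression matrix after regressing out the selected covariates; it is appended
to the donor table as ``PC1`` and enters the final model as a covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import design_matrix, log_cpm, tmm_norm_factors
from .io import PseudobulkAssay

__all__ = ["CovariateReport", "stabilize_and_pca", "associate_covariates", "hidden_confounder_pc1"]


@dataclass
class CovariateReport:
    """PC-covariate association table plus the selected covariate list."""

    associations: pd.DataFrame  # covariate, pc, statistic, p_value, covariate_class
    selected: list
    excluded_constant: list
    alpha: float


def _centered_expression(a: PseudobulkAssay) -> np.ndarray:
    factors = tmm_norm_factors(a.counts)
    Y = log_cpm(a.counts, factors)
    return Y - Y.mean(axis=1, keepdims=True)


def _pca(Z: np.ndarray, n_pcs: int):
    """PCA of a donors x genes matrix; deterministic sign convention."""
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    total = float((S**2).sum())
    scores = U[:, :n_pcs] * S[:n_pcs]
    loadings = Vt[:n_pcs].T
    for j in range(n_pcs):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    var_explained = (S[:n_pcs] ** 2) / total if total > 0 else np.zeros(n_pcs)
    return loadings, scores, var_explained


def stabilize_and_pca(a: PseudobulkAssay, n_pcs: int = 10):
    """PCA of gene-centered log-CPM expression.

    Returns ``(loadings, scores, variance_explained)`` with components in
    decreasing variance order; each component's sign is fixed so its
    largest-magnitude loading is positive.  The assay should carry the
    stringent covariate-selection gene filter (counts >= 10 in 90% of
    donors).
    """
    if n_pcs > min(a.n_genes, a.n_donors):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(genes, donors) = {min(a.n_genes, a.n_donors)}")
    Z = _centered_expression(a).T  # donors x genes
    return _pca(Z, n_pcs)


def associate_covariates(
    scores: np.ndarray,
    donors: pd.DataFrame,
    n_pcs: int | None = None,
    alpha: float = 0.05,
    covariates: list | None = None,
) -> CovariateReport:
    """Test each donor covariate against each principal component.

    Continuous covariates: Pearson correlation, two-sided p.  Categorical
    covariates (string/bool/category dtype): one-way ANOVA of PC scores by
    level.  Constant covariates are excluded and reported.  A covariate is
    selected when any of its first ``n_pcs`` tests has p < ``alpha``.
    """
    scores = np.asarray(scores, dtype=float)
    n_pcs = scores.shape[1] if n_pcs is None else min(n_pcs, scores.shape[1])
    if len(donors) != scores.shape[0]:
        raise ValueError("donor table rows do not match PC score rows")
    cols = covariates or [c for c in donors.columns if c != "donor_id"]
    rows, excluded = [], []
    for cov in cols:
        col = donors[cov]
        is_cat = col.dtype == object or str(col.dtype) == "category" or col.dtype == bool
        values = col.astype(str) if is_cat else col.to_numpy(float)
        if (len(set(values)) if is_cat else len(np.unique(values[~np.isnan(values)]))) < 2:
            excluded.append(cov)
            continue
        for j in range(n_pcs):
            pc = scores[:, j]
            if is_cat:
                groups = [pc[(values == lev).to_numpy()] for lev in sorted(set(values))]
                stat, p = stats.f_oneway(*groups)
                klass = "categorical"
            else:
                v = values
                ok = ~np.isnan(v)
                stat, p = stats.pearsonr(v[ok], pc[ok])
                klass = "continuous"
            rows.append((cov, j + 1, float(stat), float(p), klass))
    assoc = pd.DataFrame(rows, columns=["covariate", "pc", "statistic", "p_value", "covariate_class"])
    selected = sorted(assoc.loc[assoc["p_value"] < alpha, "covariate"].unique())
    return CovariateReport(associations=assoc, selected=selected, excluded_constant=excluded, alpha=alpha)


def hidden_confounder_pc1(
    a: PseudobulkAssay,
    design_covariates: list,
) -> pd.Series:
    """PC1 of the covariate-corrected expression matrix.

    Per gene, normalized (log-CPM) expression is regressed on the given
    covariates; the residuals plus the gene mean form the batch-corrected
    matrix, and PC1 scores of that matrix (sign-fixed by the
    largest-|loading| convention) are returned, indexed by donor.  With no
    covariates this reduces to ordinary PC1 of the normalized matrix.
    """
    factors = tmm_norm_factors(a.counts)
    Y = log_cpm(a.counts, factors)
    if design_covariates:
        X, _ = design_matrix(a.donors, list(design_covariates))
        Xv = X.to_numpy(float)
        beta, *_ = np.linalg.lstsq(Xv, Y.T, rcond=None)
        fitted = (Xv @ beta).T
        corrected = Y - fitted + Y.mean(axis=1, keepdims=True)
    else:
        corrected = Y
    Z = (corrected - corrected.mean(axis=1, keepdims=True)).T
    _, scores, _ = _pca(Z, 1)
    return pd.Series(scores[:, 0], index=a.donors["donor_id"].to_numpy(), name="PC1")
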