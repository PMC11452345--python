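"""Pseudobulk differential expression for age, disease and their interaction.

The model is a per-gene weighted linear model on log-CPM expression with
donor-level covariates (age, disease status, sex, pH, RIN, PMI, library
batch and a hidden-confounder PC1), trimmed-mean-of-M-values normalization
factors, and mean-variance precision weights in the style of voom.
Batch, sex and disease enter as fixed effects.  False-discovery-rate
adjustment is Benjamini-Hochberg with a contrast-dependent scope: the age
contrast is pooled across all (gene, cell type) tests, while disease and
interaction contrasts are pooled within each cell type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import PseudobulkAssay

__all__ = [
    "DesignSpec",
    "design_matrix",
    "tmm_norm_factors",
    "log_cpm",
    "voom_weights",
    "fit_gene_lm",
    "run_de",
    "covariate_corrected_expression",
    "bh_adjust",
    "DEFAULT_TERMS",
]

#: the standard covariate set of the aging model (PC1 is used when present)
DEFAULT_TERMS = ["age", "disease_status", "sex", "pH", "RIN", "PMI", "lib_batch", "PC1"]

_CONTRASTS = ("age", "disease_status", "age:disease_status")
_DEFAULT_THRESHOLD = {"age": 0.05, "disease_status": 0.1, "age:disease_status": 0.1}


@dataclass
class DesignSpec:
    """Model specification: covariate terms, tested contrast and FDR scope."""

    contrast: str = "age"
    terms: list = field(default_factory=lambda: list(DEFAULT_TERMS))
    fdr_scope: str | None = None  # derived from contrast when None
    de_threshold: float | None = None
    use_weights: bool = True

    def __post_init__(self) -> None:
        if self.contrast not in _CONTRASTS:
            raise ValueError(f"contrast must be one of {_CONTRASTS}, got {self.contrast!r}")
        if self.contrast == "age:disease_status" and self.contrast not in self.terms:
            self.terms = list(self.terms) + [self.contrast]
        base = self.contrast.split(":")
        for t in base:
            if t not in self.terms:
                raise ValueError(f"contrast term {t!r} is not among the design terms {self.terms}")
        if self.fdr_scope is None:
            self.fdr_scope = "global_across_cell_types" if self.contrast == "age" else "within_cell_type"
        if self.fdr_scope not in ("global_across_cell_types", "within_cell_type"):
            raise ValueError(f"unknown fdr_scope {self.fdr_scope!r}")
        if self.de_threshold is None:
            self.de_threshold = _DEFAULT_THRESHOLD[self.contrast]


def design_matrix(
    donors: pd.DataFrame, terms: list
) -> tuple[pd.DataFrame, dict]:
    """Build a design matrix from donor covariates.

    Continuous terms enter as numeric columns; ``sex`` and ``lib_batch`` are
    expanded to drop-first indicator columns; ``a:b`` terms are products of
    the two (already built) columns.  Missing RIN values are imputed with the
    cohort median; any other missing value is an error.  Returns the design
    (with intercept) and a mapping from term name to its design columns.
    """
    donors = donors.reset_index(drop=True)
    X = pd.DataFrame({"intercept": np.ones(len(donors))})
    term_cols: dict[str, list] = {"intercept": ["intercept"]}
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            cols = []
            for ca in term_cols[a]:
                for cb in term_cols[b]:
                    name = f"{ca}:{cb}"
                    X[name] = X[ca] * X[cb]
                    cols.append(name)
            term_cols[term] = cols
            continue
        if term not in donors.columns:
            raise ValueError(f"design term {term!r} is not a donor covariate")
        col = donors[term]
        if col.dtype == object or str(col.dtype) == "category" or col.dtype == bool:
            levels = sorted(col.astype(str).unique())
            cols = []
            for lev in levels[1:]:
                name = f"{term}_{lev}"
                X[name] = (col.astype(str) == lev).astype(float)
                cols.append(name)
            if not cols:  # constant categorical carries no information
                warnings.warn(f"covariate {term!r} is constant; dropped from the design")
            term_cols[term] = cols
        else:
            v = col.to_numpy(dtype=float)
            if np.isnan(v).any():
                if term == "RIN":
                    v = np.where(np.isnan(v), np.nanmedian(v), v)
                else:
                    raise ValueError(f"covariate {term!r} has missing values")
            if np.ptp(v) == 0 and term != "intercept":
                warnings.warn(f"covariate {term!r} is constant; dropped from the design")
                term_cols[term] = []
                continue
            X[term] = v
            term_cols[term] = [term]
    _check_full_rank(X)
    return X, term_cols


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        _, R = np.linalg.qr(A)
        aliased = [
            X.columns[j]
            for j in range(A.shape[1])
            if j >= R.shape[0] or abs(R[j, j]) < 1e-8
        ]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")


def tmm_norm_factors(
    counts: pd.DataFrame | np.ndarray,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, one per donor column.

    The reference donor is the one whose upper-quartile of library-scaled
    counts is closest to the mean upper-quartile.  For each donor, M- and
    A-values over genes positive in both donor and reference are doubly
    trimmed (default 30% on M, 5% on A, from each tail), and the factor is
    2 to the precision-weighted mean M.  Factors are rescaled to geometric
    mean 1, so they carry only composition differences, not depth.
    """
    C = np.asarray(counts, dtype=float)
    lib = C.sum(axis=0)
    if (lib <= 0).any():
        bad = np.flatnonzero(lib <= 0)
        raise ValueError(f"donors with zero library size at columns {bad.tolist()}")
    if C.shape[1] < 2:
        raise ValueError("TMM requires at least two donors")
    f75 = np.quantile(C / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(C.shape[1])
    xr, Nr = C[:, ref], lib[ref]
    for d in range(C.shape[1]):
        if d == ref:
            continue
        x, N = C[:, d], lib[d]
        both = (x > 0) & (xr > 0)
        if both.sum() < 10:
            continue
        p, pr = x[both] / N, xr[both] / Nr
        M = np.log2(p / pr)
        A = 0.5 * np.log2(p * pr)
        w = (N - x[both]) / (N * x[both]) + (Nr - xr[both]) / (Nr * xr[both])
        loM, hiM = np.quantile(M, [logratio_trim, 1 - logratio_trim])
        loA, hiA = np.quantile(A, [abs_trim, 1 - abs_trim])
        keep = (M >= loM) & (M <= hiM) & (A >= loA) & (A <= hiA)
        if keep.sum() == 0:
            continue
        factors[d] = 2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


def log_cpm(
    counts: pd.DataFrame | np.ndarray,
    factors: np.ndarray | None = None,
    prior: float = 0.5,
) -> np.ndarray:
    """log2 counts per million with a prior count and effective library sizes.

    ``value(g, d) = log2((count + prior) / (libsize * factor + 1) * 1e6)``.
    """
    C = np.asarray(counts, dtype=float)
    lib = C.sum(axis=0)
    if factors is None:
        factors = np.ones(C.shape[1])
    factors = np.asarray(factors, dtype=float)
    if (factors <= 0).any():
        raise ValueError("normalization factors must be positive")
    eff = lib * factors + 1.0
    return np.log2((C + prior) / eff[None, :] * 1e6)


def voom_weights(
    logcpm: np.ndarray,
    counts: pd.DataFrame | np.ndarray,
    design: np.ndarray | None = None,
    factors: np.ndarray | None = None,
    span: float = 0.5,
) -> np.ndarray:
    """Mean-variance precision weights from the empirical sqrt-sd trend.

    Per gene, the square root of the residual standard deviation from an
    unweighted fit of ``design`` (intercept-only when omitted) is regressed
    against average log2 count with lowess (default span 0.5).  The trend is
    then evaluated at each observation's fitted log2 count and inverted to
    the fourth power to give a positive weight per observation.
    """
    Y = np.asarray(logcpm, dtype=float)
    C = np.asarray(counts, dtype=float)
    n_genes, n_donors = Y.shape
    if n_genes < 10:
        warnings.warn("fewer than 10 genes: mean-variance trend is unreliable; unit weights used")
        return np.ones_like(Y)
    lib = C.sum(axis=0)
    if factors is None:
        factors = np.ones(n_donors)
    eff = lib * np.asarray(factors, float) + 1.0

    X = np.ones((n_donors, 1)) if design is None else np.asarray(design, float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    dof = n_donors - X.shape[1]
    if dof <= 0:
        warnings.warn("no residual degrees of freedom; unit weights used")
        return np.ones_like(Y)
    resid = Y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / dof)
    if np.allclose(sigma, 0):
        warnings.warn("degenerate mean-variance trend (all residual sds zero); unit weights used")
        return np.ones_like(Y)

    sx = Y.mean(axis=1) + np.mean(np.log2(eff)) - np.log2(1e6)  # average log2 count
    sy = np.sqrt(sigma)
    trend = lowess(sy, sx, frac=span, delta=0.01 * np.ptp(sx), return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)
    fitted_logcount = fitted + np.log2(eff)[None, :] - np.log2(1e6)
    l = np.interp(fitted_logcount, tx, ty)  # constant extrapolation at edges
    return 1.0 / l**4


def _wls_batch(Y: np.ndarray, X: np.ndarray, W: np.ndarray, contrast_col: int):
    """Weighted least squares for many genes at once.

    Y, W are (genes x donors); X is (donors x terms).  Returns the contrast
    coefficient, its standard error, t, two-sided p and residual df.
    """
    n_genes, n_donors = Y.shape
    p = X.shape[1]
    dof = n_donors - p
    XtW = X.T[None, :, :] * W[:, None, :]  # (g, p, d)
    XtWX = XtW @ X
    XtWy = XtW @ Y[:, :, None]
    beta = np.linalg.solve(XtWX, XtWy)[..., 0]
    resid = Y - beta @ X.T
    s2 = (W * resid**2).sum(axis=1) / dof
    inv = np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(s2[:, None] * np.diagonal(inv, axis1=1, axis2=2), 0.0))
    est, ses = beta[:, contrast_col], se[:, contrast_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ses > 0, est / ses, np.inf * np.sign(est))
    pval = 2 * stats.t.sf(np.abs(t), dof) if dof > 0 else np.full(n_genes, np.nan)
    return est, ses, t, pval, dof


def fit_gene_lm(
    y: np.ndarray,
    design: pd.DataFrame | np.ndarray,
    weights: np.ndarray | None = None,
    contrast: str | int = 1,
) -> dict:
    """Weighted least-squares fit of one gene; returns the contrast row.

    ``contrast`` may be a design column name (when ``design`` is a
    DataFrame) or a column index.
    """
    Xdf = design if isinstance(design, pd.DataFrame) else None
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few donors for the design (need terms + 2)")
    _check_full_rank(Xdf if Xdf is not None else pd.DataFrame(X, columns=[str(i) for i in range(X.shape[1])]))
    if isinstance(contrast, str):
        if Xdf is None or contrast not in Xdf.columns:
            raise ValueError(f"contrast column {contrast!r} not in design")
        cidx = list(Xdf.columns).index(contrast)
    else:
        cidx = int(contrast)
    W = np.ones((1, len(y))) if weights is None else np.asarray(weights, float)[None, :]
    est, se, t, pv, dof = _wls_batch(y[None, :], X, W, cidx)
    return {
        "estimate": float(est[0]),
        "std_error": float(se[0]),
        "t_statistic": float(t[0]),
        "p_value": float(pv[0]),
        "df": int(dof),
    }


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs are left untested."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _contrast_column(term_cols: dict, contrast: str) -> str:
    cols = term_cols.get(contrast, [])
    if len(cols) != 1:
        raise ValueError(
            f"contrast {contrast!r} does not map to a single design column (got {cols}); "
            "multi-level contrasts are not supported"
        )
    return cols[0]


def run_de(
    assays: list[PseudobulkAssay],
    spec: DesignSpec | None = None,
) -> pd.DataFrame:
    """Fit every gene in every assay and adjust p-values per the FDR scope.

    Each assay must already be gene-filtered (``de`` preset).  Returns one
    row per (gene, cell type): estimate (log2 per unit of contrast), standard
    error, t, p, fdr, mean log expression, direction and an ``is_de`` flag at
    ``spec.de_threshold``.  Genes with fewer than 2 residual degrees of
    freedom are recorded as untested (NaN p and fdr).
    """
    spec = spec or DesignSpec()
    frames = []
    for a in assays:
        if a is None:
            continue
        terms = [t for t in spec.terms if ":" in t or t in a.donors.columns]
        X, term_cols = design_matrix(a.donors, terms)
        cidx = list(X.columns).index(_contrast_column(term_cols, spec.contrast))
        Xv = X.to_numpy(float)
        factors = tmm_norm_factors(a.counts)
        Y = log_cpm(a.counts, factors)
        W = voom_weights(Y, a.counts, design=Xv, factors=factors) if spec.use_weights else np.ones_like(Y)
        dof = Xv.shape[0] - Xv.shape[1]
        if dof < 2:
            est = np.full(a.n_genes, np.nan)
            se = t = pv = est
        else:
            est, se, t, pv, dof = _wls_batch(Y, Xv, W, cidx)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": a.counts.index,
                    "cell_type": a.cell_type if a.cell_type is not None else "full",
                    "estimate": est,
                    "std_error": se,
                    "t_statistic": t,
                    "p_value": pv,
                    "mean_log_expr": Y.mean(axis=1),
                    "direction": np.sign(est).astype(int),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["gene_id", "cell_type", "estimate", "std_error", "t_statistic",
                     "p_value", "fdr", "mean_log_expr", "direction", "is_de"]
        )
    de = pd.concat(frames, ignore_index=True)
    if spec.fdr_scope == "global_across_cell_types":
        de["fdr"] = bh_adjust(de["p_value"].to_numpy())
    else:
        de["fdr"] = np.nan
        for ct, idx in de.groupby("cell_type", sort=False).groups.items():
            de.loc[idx, "fdr"] = bh_adjust(de.loc[idx, "p_value"].to_numpy())
    de["is_de"] = de["fdr"] < spec.de_threshold
    return de


def covariate_corrected_expression(
    assay: PseudobulkAssay,
    keep_term: str = "age",
    terms: list | None = None,
) -> pd.DataFrame:
    """Normalized expression with all nuisance covariates regressed out.

    Fits each gene's log-CPM on the full design, then removes the fitted
    contribution of every term except the intercept and ``keep_term`` (used
    for trajectory visualization and the transcriptomic clock).
    """
    terms = [t for t in (terms or DEFAULT_TERMS) if ":" in t or t in assay.donors.columns]
    if keep_term not in terms:
        raise ValueError(f"keep_term {keep_term!r} is not among the design terms {terms}")
    X, term_cols = design_matrix(assay.donors, terms)
    factors = tmm_norm_factors(assay.counts) if assay.n_donors >= 2 else None
    Y = log_cpm(assay.counts, factors)
    Xv = X.to_numpy(float)
    beta, *_ = np.linalg.lstsq(Xv, Y.T, rcond=None)
    nuisance_cols = [
        c for t, cols in term_cols.items() if t not in ("intercept", keep_term) for c in cols
    ]
    idx = [list(X.columns).index(c) for c in nuisance_cols]
    corrected = Y - (Xv[:, idx] @ beta[idx, :]).T
    return pd.DataFrame(corrected, index=assay.counts.index, columns=assay.counts.columns)
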