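"""Cell-type composition: per-donor proportions and age-trend regression.

Each donor's cell-type proportions are the nucleus counts of a cell type
divided by the donor's total nuclei.  Per cell type, a covariate-adjusted
linear regression of proportion on age (controlling for sex, disease
status, pH, RIN, PMI and library batch) tests for composition drift, with
Benjamini-Hochberg adjustment across cell types and significance called at
FDR < 0.05.  An optional logit transform of the response is available for
boundary-heavy data but is off by default, mirroring the plain linear model
on raw proportions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust, design_matrix

__all__ = ["cell_proportions", "composition_trend", "COMPOSITION_COVARIATES"]

COMPOSITION_COVARIATES = ["sex", "disease_status", "pH", "RIN", "PMI", "lib_batch"]


def cell_proportions(nuclei: pd.DataFrame) -> pd.DataFrame:
    """Per-donor cell-type proportions from nucleus metadata.

    Requires ``donor_id`` and ``cell_type`` columns.  Returns donors (rows,
    in first-seen order) x cell types (columns); rows sum to 1 exactly in
    rational arithmetic before float conversion.  Donors with zero nuclei
    cannot appear in the metadata and are therefore naturally excluded.
    """
    for col in ("donor_id", "cell_type"):
        if col not in nuclei.columns:
            raise ValueError(f"nucleus metadata lacks required column {col!r}")
    tab = pd.crosstab(nuclei["donor_id"], nuclei["cell_type"])
    donors_order = list(dict.fromkeys(nuclei["donor_id"]))
    ct_order = list(dict.fromkeys(nuclei["cell_type"]))
    tab = tab.loc[donors_order, ct_order]
    return tab.div(tab.sum(axis=1), axis=0)


def composition_trend(
    props: pd.DataFrame,
    donors: pd.DataFrame,
    covariates: list | None = None,
    alpha: float = 0.05,
    logit: bool = False,
) -> pd.DataFrame:
    """Covariate-adjusted linear age trend per cell type.

    ``props`` is donors x cell types (as from :func:`cell_proportions`);
    ``donors`` must cover its rows.  Per cell type the proportion (or its
    logit when ``logit``) is regressed on age plus the covariates; p-values
    are BH-adjusted across cell types and flagged at FDR < ``alpha``.  A
    constant response gives slope exactly 0 with p = 1.
    """
    donors = donors.set_index("donor_id").loc[props.index].reset_index()
    covariates = covariates if covariates is not None else [c for c in COMPOSITION_COVARIATES if c in donors.columns]
    terms = ["age"] + [c for c in covariates if c != "age"]
    X, _ = design_matrix(donors, terms)
    Xv = X.to_numpy(float)
    age_col = list(X.columns).index("age")
    dof = Xv.shape[0] - Xv.shape[1]
    if dof < 1:
        raise ValueError("too few donors for the composition design")
    XtX_inv = np.linalg.inv(Xv.T @ Xv)
    rows = []
    for ct in props.columns:
        y = props[ct].to_numpy(float)
        if logit:
            eps = 0.5 / max(len(y), 1)
            y = np.log(np.clip(y, eps, 1 - eps) / (1 - np.clip(y, eps, 1 - eps)))
        if np.ptp(y) == 0:
            rows.append((ct, 0.0, 0.0, 0.0, 1.0))
            continue
        beta = XtX_inv @ (Xv.T @ y)
        resid = y - Xv @ beta
        s2 = resid @ resid / dof
        se = np.sqrt(s2 * XtX_inv[age_col, age_col])
        t = beta[age_col] / se if se > 0 else 0.0
        p = 2 * stats.t.sf(abs(t), dof) if se > 0 else 1.0
        rows.append((ct, beta[age_col], se, t, p))
    out = pd.DataFrame(rows, columns=["cell_type", "age_slope", "std_error", "t_statistic", "p_value"])
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["fdr"] < alpha
    return out
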