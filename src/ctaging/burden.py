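"""Downsampling procedure ranking cell types by transcriptomic aging burden.

DE-gene counts across cell types confound aging burden with statistical
power (nucleus numbers differ by orders of magnitude).  The procedure here
equalizes power by drawing the same number of nuclei (default 5,000) from
every cell type, repeating the draw (default 10 replicates), rerunning the
age differential-expression analysis on each subsample, and comparing the
resulting DE-gene counts between cell types with a two-sided Mann-Whitney
U-test followed by Benjamini-Hochberg correction over all pairs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DesignSpec, run_de
from .io import (
    NucleusCountMatrix,
    PseudobulkAssay,
    filter_pseudobulk_genes,
    preset_params,
)

__all__ = ["BurdenResult", "downsample_and_count", "mann_whitney_exact", "compare_burden"]


@dataclass
class BurdenResult:
    """Replicate DE-gene counts per cell type plus the pairwise comparisons."""

    counts: pd.DataFrame  # cell types x replicates, integer DE-gene counts
    mean_counts: pd.Series
    ranks: pd.Series  # 1 = highest mean count; ties broken by label order
    pairwise: pd.DataFrame | None
    excluded: list
    n_nuclei: int
    n_reps: int
    seed: int


def _midranks(z: np.ndarray) -> np.ndarray:
    return stats.rankdata(z, method="average")


def mann_whitney_exact(x, y, exact_limit: int = 16) -> tuple[float, float]:
    """Two-sided Mann-Whitney U-test with an exact small-sample branch.

    U is computed from midrank sums.  When ``nx + ny <= exact_limit`` the
    p-value is exact: all C(nx+ny, nx) assignments of the pooled (mid)ranks
    are enumerated and ``p = P(|U' - nx*ny/2| >= |U - nx*ny/2|)``, so
    identical samples give p = 1.  Larger samples use the normal
    approximation with tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u = ranks[:nx].sum() - nx * (nx + 1) / 2
    mu = nx * ny / 2.0

    if nx + ny <= exact_limit:
        n = nx + ny
        obs = abs(u - mu)
        hits = total = 0
        base = (np.arange(1, nx + 1)).sum()
        for comb in itertools.combinations(range(n), nx):
            u_prime = ranks[list(comb)].sum() - base
            total += 1
            if abs(u_prime - mu) >= obs - 1e-9:
                hits += 1
        return float(u), hits / total

    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return float(u), 1.0
    diff = u - mu
    z = (abs(diff) - 0.5) / math.sqrt(sigma2) if diff != 0 else 0.0
    return float(u), min(1.0, 2 * stats.norm.sf(max(z, 0.0)))


def compare_burden(counts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise Mann-Whitney comparisons of replicate DE-gene counts.

    ``counts`` is cell types x replicates.  Returns one row per unordered
    pair with U, two-sided p and BH-adjusted p across the pair pool; the
    focal "top cell type vs each other" rows can be selected on ``cell_type_a``.
    """
    from .diffexpr import bh_adjust

    if counts.shape[0] < 2:
        raise ValueError("need at least 2 cell types to compare")
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 replicates per cell type")
    rows = []
    for a, b in itertools.combinations(counts.index, 2):
        u, p = mann_whitney_exact(counts.loc[a].to_numpy(), counts.loc[b].to_numpy())
        rows.append((a, b, u, p))
    out = pd.DataFrame(rows, columns=["cell_type_a", "cell_type_b", "U", "p_value"])
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["fdr"] < alpha
    return out


def downsample_and_count(
    m: NucleusCountMatrix,
    donors: pd.DataFrame,
    spec: DesignSpec | None = None,
    n_nuclei: int = 5000,
    n_reps: int = 10,
    seed: int = 0,
    allow_deficit: bool = False,
    stratify_by_donor: bool = False,
    gene_filter: dict | None = None,
) -> BurdenResult:
    """Equal-size downsampling of nuclei per cell type, repeated age DE.

    For each replicate ``r`` a uniform without-replacement sample of
    ``n_nuclei`` nuclei per cell type is drawn with seed ``seed XOR r``,
    pseudobulk is rebuilt, the age DE analysis is rerun (FDR pooled globally
    across cell types within the replicate), and the DE-gene count per cell
    type is recorded.  Cell types with fewer than ``n_nuclei`` nuclei are
    excluded with a warning unless ``allow_deficit``, in which case all their
    nuclei are used and the count is flagged non-comparable.
    """
    spec = spec or DesignSpec(contrast="age")
    gene_filter = gene_filter if gene_filter is not None else preset_params("de")
    ct_sizes = m.nuclei["cell_type"].value_counts()
    cell_types = list(dict.fromkeys(m.nuclei["cell_type"]))
    excluded, deficit = [], []
    for ct in cell_types:
        if ct_sizes[ct] < n_nuclei:
            if allow_deficit:
                deficit.append(ct)
            else:
                excluded.append(ct)
    included = [ct for ct in cell_types if ct not in excluded]
    if excluded:
        warnings.warn(
            f"cell types below {n_nuclei} nuclei excluded from burden ranking: {excluded}"
        )
    if not included:
        raise ValueError(f"no cell type has {n_nuclei} nuclei")

    import scipy.sparse as sp

    ct_arr = m.nuclei["cell_type"].to_numpy()
    donor_arr = m.nuclei["donor_id"].to_numpy()
    donor_ids = list(donors["donor_id"])
    donor_pos = {d: i for i, d in enumerate(donor_ids)}
    unknown = sorted(set(donor_arr) - set(donor_ids))
    if unknown:
        raise ValueError(f"nuclei reference donors absent from the donor table: {unknown}")
    donor_idx = np.array([donor_pos[d] for d in donor_arr])
    n_d = len(donor_ids)
    gene_index = pd.Index(m.gene_ids, name="gene_id")
    counts = pd.DataFrame(0, index=pd.Index(included, name="cell_type"), columns=range(n_reps))
    for r in range(n_reps):
        rng = np.random.default_rng(seed ^ r)
        take = []
        for ct in included:
            idx = np.flatnonzero(ct_arr == ct)
            k = min(n_nuclei, len(idx))
            if stratify_by_donor and k < len(idx):
                # proportional allocation across donors, remainder at random
                sel = []
                d_of = donor_arr[idx]
                uniq = pd.unique(d_of)
                quota = {d: int(k * (d_of == d).sum() / len(idx)) for d in uniq}
                for d in uniq:
                    pool = idx[d_of == d]
                    sel.append(rng.choice(pool, size=min(quota[d], len(pool)), replace=False))
                sel = np.concatenate(sel) if sel else np.empty(0, int)
                rest = np.setdiff1d(idx, sel)
                extra = rng.choice(rest, size=k - len(sel), replace=False)
                take.append(np.concatenate([sel, extra]))
            else:
                take.append(rng.choice(idx, size=k, replace=False) if k < len(idx) else idx)
        # one sparse indicator maps sampled nuclei to (cell type, donor)
        # columns, so the replicate pseudobulk is a single exact matmul
        rows = np.concatenate(take)
        ct_col = np.concatenate([np.full(len(t), i) for i, t in enumerate(take)])
        cols = ct_col * n_d + donor_idx[rows]
        ind = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int64), (rows, cols)), shape=(m.n_nuclei, len(included) * n_d)
        )
        agg = np.asarray((m.counts @ ind).todense())
        assays = []
        for i, ct in enumerate(included):
            block = agg[:, i * n_d : (i + 1) * n_d]
            contributed = np.bincount(donor_idx[take[i]], minlength=n_d)
            assays.append(
                PseudobulkAssay(
                    cell_type=ct,
                    counts=pd.DataFrame(block, index=gene_index, columns=donor_ids),
                    donors=donors.reset_index(drop=True),
                    nuclei_contributed=pd.Series(contributed, index=donor_ids, name="nuclei"),
                )
            )
        assays = [filter_pseudobulk_genes(a, **gene_filter) for a in assays]
        de = run_de([a for a in assays if a is not None], spec)
        if len(de):
            per_ct = de.groupby("cell_type")["is_de"].sum()
            for ct in included:
                counts.loc[ct, r] = int(per_ct.get(ct, 0))

    mean_counts = counts.mean(axis=1)
    order = sorted(included, key=lambda ct: (-mean_counts[ct], ct))
    ranks = pd.Series({ct: i + 1 for i, ct in enumerate(order)}, name="rank")
    pairwise = compare_burden(counts) if len(included) >= 2 and n_reps >= 2 else None
    if deficit and pairwise is not None:
        pairwise["non_comparable"] = pairwise["cell_type_a"].isin(deficit) | pairwise[
            "cell_type_b"
        ].isin(deficit)
    return BurdenResult(
        counts=counts,
        mean_counts=mean_counts,
        ranks=ranks[included],
        pairwise=pairwise,
        excluded=excluded,
        n_nuclei=n_nuclei,
        n_reps=n_reps,
        seed=seed,
    )
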