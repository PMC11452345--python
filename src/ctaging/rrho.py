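"""Stratified rank-rank hypergeometric overlap maps for signed DE rankings.

Two differential-expression signatures are each collapsed to a signed
ranking metric — the log2 fold change times the negative base-10 log of the
uncorrected p-value — and compared on a grid of rank-threshold pairs.  Each
grid cell scores the overlap of two gene sets by the hypergeometric upper
tail P(X >= k) (computed in log space) and stores the signed -log10 p:
positive in concordant quadrants (up-up from the top of both rankings,
down-down from the bottom of both) and negative in discordant quadrants
(top of one against bottom of the other).  The quadrant of a cell is set by
each list's sign-split index, the first rank at which the metric turns
negative.

Convention note: the "bottom t" set at threshold t has size t (genes ranked
N-t+1..N), so the (N, N) corner of every quadrant compares the two full
lists and scores exactly zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RankedGeneList", "RRHOMap", "ranking_metric", "rrho_map"]

_P_FLOOR = 1e-300  # p-values are floored here pre-log to keep maps finite


@dataclass
class RankedGeneList:
    """Genes ordered by a signed metric, descending; ties broken by gene id."""

    genes: np.ndarray  # ordering, best (most positive metric) first
    metric: np.ndarray  # aligned with `genes`
    sign_split_index: int  # first position where the metric is negative

    @property
    def n(self) -> int:
        return len(self.genes)

    def restrict(self, universe: set) -> "RankedGeneList":
        keep = np.array([g in universe for g in self.genes])
        genes, metric = self.genes[keep], self.metric[keep]
        return RankedGeneList(genes, metric, int(np.searchsorted(-metric, 0, side="right")))


@dataclass
class RRHOMap:
    """Grid of signed -log10 hypergeometric tail probabilities."""

    grid: np.ndarray  # thresholds_a x thresholds_b
    thresholds: np.ndarray  # step, 2*step, ..., floor(N/step)*step
    step: int
    n_genes: int
    split_a: int
    split_b: int

    def quadrant(self, i: int, j: int) -> str:
        ti, tj = self.thresholds[i], self.thresholds[j]
        side_a = "up" if ti <= self.split_a else "down"
        side_b = "up" if tj <= self.split_b else "down"
        return f"{side_a}-{side_b}"


def ranking_metric(de: pd.DataFrame) -> RankedGeneList:
    """Signed ranking metric: estimate times -log10 of the uncorrected p.

    Genes with missing p-values are dropped with a warning; p is floored at
    1e-300 before the log.  Ordering is by metric descending with ties broken
    by gene id, so the list is deterministic.
    """
    ok = de["p_value"].notna() & de["estimate"].notna()
    if (~ok).any():
        warnings.warn(f"dropped {int((~ok).sum())} genes with missing p-values or estimates")
    sub = de[ok]
    p = np.maximum(sub["p_value"].to_numpy(float), _P_FLOOR)
    metric = sub["estimate"].to_numpy(float) * (-np.log10(p))
    order = np.lexsort((sub["gene_id"].to_numpy(), -metric))
    genes = sub["gene_id"].to_numpy(object)[order]
    metric = metric[order]
    split = int(np.searchsorted(-metric, 0, side="right"))  # first metric < 0
    return RankedGeneList(genes=genes, metric=metric, sign_split_index=split)


def _cum_counts(pa: np.ndarray, pb: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """C[i, j] = number of genes with pa < thresholds[i] and pb < thresholds[j]."""
    # half-integer edges: histogram2d closes its last bin on the right, which
    # would break the strict "< threshold" semantics for integer positions
    edges = np.concatenate([[-0.5], thresholds - 0.5])
    H, _, _ = np.histogram2d(pa, pb, bins=[edges, edges])
    return H.cumsum(axis=0).cumsum(axis=1)


def rrho_map(a: RankedGeneList, b: RankedGeneList, step: int | None = None) -> RRHOMap:
    """Stratified rank-rank hypergeometric overlap map of two rankings.

    The gene universes are intersected (with a warning when they differ; an
    error when disjoint).  For threshold pair (ti, tj) the overlap k of the
    relevant sets (prefixes for up-up, bottom-ti/tj sets for down-down, mixed
    in the discordant quadrants) is scored by the upper tail of
    Hypergeometric(N, K=ti, draws=tj); the cell holds the signed -log10 p.
    """
    universe_a, universe_b = set(a.genes), set(b.genes)
    common = universe_a & universe_b
    if not common:
        raise ValueError("the two rankings share no genes")
    if common != universe_a or common != universe_b:
        warnings.warn(
            f"gene universes differ ({len(universe_a)} vs {len(universe_b)}); "
            f"restricted to the {len(common)} shared genes"
        )
        a, b = a.restrict(common), b.restrict(common)
    N = a.n
    if N < 10:
        raise ValueError(f"need at least 10 shared genes, got {N}")
    if step is None:
        step = math.ceil(math.sqrt(N))
    if step < 1:
        raise ValueError("step must be a positive integer")
    thresholds = np.arange(step, N + 1, step)

    pos_a = {g: i for i, g in enumerate(a.genes)}
    order = np.array([pos_a[g] for g in b.genes])  # position in a of b's i-th gene
    pa = np.empty(N, dtype=float)  # pa[j], pb[j] = positions of one gene in each list
    pa[:] = order
    pb = np.arange(N, dtype=float)
    # reversed positions turn "bottom t" membership into a prefix condition
    ra, rb = (N - 1) - pa, (N - 1) - pb

    k_uu = _cum_counts(pa, pb, thresholds)
    k_dd = _cum_counts(ra, rb, thresholds)
    k_ud = _cum_counts(pa, rb, thresholds)
    k_du = _cum_counts(ra, pb, thresholds)

    ti = thresholds[:, None].astype(int)
    tj = thresholds[None, :].astype(int)
    in_up_a = ti <= a.sign_split_index
    in_up_b = tj <= b.sign_split_index
    k = np.where(
        in_up_a & in_up_b, k_uu, np.where(~in_up_a & ~in_up_b, k_dd, np.where(in_up_a, k_ud, k_du))
    ).astype(int)
    concordant = in_up_a == in_up_b

    logp = stats.hypergeom.logsf(k - 1, N, ti, tj)  # log P(X >= k)
    neglog10 = np.minimum(-logp / math.log(10), -math.log10(_P_FLOOR))
    neglog10 = np.where(k == 0, 0.0, neglog10)  # P(X >= 0) = 1 exactly
    grid = np.where(concordant, neglog10, -neglog10)
    return RRHOMap(
        grid=grid,
        thresholds=thresholds,
        step=step,
        n_genes=N,
        split_a=a.sign_split_index,
        split_b=b.sign_split_index,
    )
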