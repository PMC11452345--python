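"""Gene-set comparison machinery for cross-dataset and disease convergence.

Implements the symmetric overlap index O(A, B) = (|A∩B|/|A| + |A∩B|/|B|)/2,
one-sided Fisher (hypergeometric) enrichment tests of two gene sets against a
tested-gene background, Spearman correlation and direction concordance of
shared genes' effect sizes, the 15th-percentile p-value eligibility rule for
underpowered replication cell types, and a driver that compares two
differential-expression signatures cell type by cell type with direction
splitting and pooled FDR adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "OverlapResult",
    "overlap_index",
    "hypergeom_upper_tail",
    "fisher_overlap",
    "effect_concordance",
    "replication_eligibility",
    "compare_signatures",
]


@dataclass
class OverlapResult:
    """Overlap of two gene sets over a background universe."""

    set_a_size: int
    set_b_size: int
    background_size: int
    n_overlap: int
    overlap_index: float
    odds_ratio: float
    fisher_p: float
    fdr: float | None = None
    spearman_rho: float | None = None
    spearman_p: float | None = None
    concordance_pct: float | None = None


def overlap_index(A, B) -> float:
    """Symmetric set-similarity: mean of the overlap's share of each set.

    ``O = (|A∩B|/|A| + |A∩B|/|B|)/2``; 0 by convention when either set is
    empty.  Unlike Jaccard, each set is weighted equally even when their
    sizes differ greatly.
    """
    A, B = set(A), set(B)
    if not A or not B:
        return 0.0
    k = len(A & B)
    return (k / len(A) + k / len(B)) / 2


def hypergeom_upper_tail(k, N, K, n):
    """P(X >= k) for X ~ Hypergeometric(N, K, n); broadcasts over arrays."""
    return stats.hypergeom.sf(np.asarray(k) - 1, N, K, n)


def fisher_overlap(A, B, background) -> OverlapResult:
    """One-sided enrichment test of two gene sets over a background.

    Genes outside the background are dropped with a warning (mirroring the
    removal of genes not tested in the discovery data).  The p-value is the
    hypergeometric upper tail P(X >= |A∩B|); the odds ratio is the sample
    odds ratio ``a*d/(b*c)`` with infinity when ``b*c = 0`` and ``a*d > 0``.
    """
    background = set(background)
    if not background:
        raise ValueError("background universe is empty")
    A, B = set(A), set(B)
    strayA, strayB = A - background, B - background
    if strayA or strayB:
        warnings.warn(
            f"dropped genes outside the background: {len(strayA)} from A, {len(strayB)} from B"
        )
        A, B = A & background, B & background
    N = len(background)
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = N - a - b - c
    p = float(hypergeom_upper_tail(a, N, len(A), len(B)))
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan if a * d == 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    return OverlapResult(
        set_a_size=len(A),
        set_b_size=len(B),
        background_size=N,
        n_overlap=a,
        overlap_index=overlap_index(A, B) if A and B else 0.0,
        odds_ratio=float(odds),
        fisher_p=min(p, 1.0),
    )


_PERM_CACHE: dict = {}


def _spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact permutation two-sided p for Spearman rho at small n.

    All n! orderings are scored at once (Pearson correlation of midranks,
    vectorized over a cached permutation table), so the enumeration stays
    fast up to n = 9.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if n not in _PERM_CACHE:
        _PERM_CACHE[n] = np.array(list(itertools.permutations(range(n))))
    perms = _PERM_CACHE[n]
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    rhos = (ry[perms] - ry.mean()) @ rxc / denom
    obs = float(rhos[0] if (perms[0] == np.arange(n)).all() else (ryc @ rxc) / denom)
    p = float(np.mean(np.abs(rhos) >= abs(obs) - 1e-12))
    return obs, p


def effect_concordance(
    lfc_a: pd.Series | dict,
    lfc_b: pd.Series | dict,
    exact_limit: int = 9,
) -> tuple[float | None, float | None, float]:
    """Spearman correlation and sign concordance of shared genes' effects.

    Genes are matched by identifier.  Returns ``(rho, p, concordance_pct)``;
    rho is None (undefined) with fewer than 3 shared genes, while the
    concordance percentage — the share of matched genes with equal effect
    sign, zeros counted as discordant — is always computed.  The p-value is
    an exact permutation enumeration for n <= ``exact_limit``, otherwise the
    t-approximation.
    """
    a = pd.Series(lfc_a, dtype=float)
    b = pd.Series(lfc_b, dtype=float)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        return None, None, 0.0
    x = a[shared].to_numpy()
    y = b[shared].to_numpy()
    conc = 100.0 * np.mean((np.sign(x) == np.sign(y)) & (np.sign(x) != 0))
    if len(shared) < 3:
        return None, None, float(conc)
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        return None, None, float(conc)
    if len(shared) <= exact_limit:
        rho, p = _spearman_exact(x, y)
    else:
        rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), float(conc)


def replication_eligibility(
    p_values, percentile: float = 15.0, cutoff: float = 0.1
) -> bool:
    """Eligibility rule for underpowered replication cell types.

    True iff the given percentile (linear-interpolation quantile; default
    15th) of nominal p-values is strictly below ``cutoff`` — a left-shifted
    p-value distribution signals real signal despite small sample size.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    return bool(np.percentile(p, percentile) < cutoff)


def _de_sets(de: pd.DataFrame, threshold: float, on: str) -> pd.DataFrame:
    col = "fdr" if on == "fdr" else "p_value"
    return de[de[col] < threshold]


def compare_signatures(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    cell_type_map: dict | None = None,
    direction: str = "both",
    threshold_a: float = 0.05,
    threshold_b: float = 0.05,
    select_a: str = "fdr",
    select_b: str = "fdr",
    background: str = "discovery",
) -> pd.DataFrame:
    """Compare two DE signatures cell type by cell type.

    For each matched cell-type pair the replication table is restricted to
    the discovery-tested background (or the intersection of both tested
    universes with ``background='intersection'``), DE sets are formed at the
    given thresholds (on FDR or nominal p per ``select_*``), optionally split
    by direction, and overlap index, Fisher enrichment and effect
    concordance are computed.  Fisher p-values are BH-adjusted across all
    (cell type x direction) comparisons of the run.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError("direction must be 'up', 'down' or 'both'")
    cts_a = de_a["cell_type"].unique()
    cell_type_map = cell_type_map or {ct: ct for ct in cts_a}
    directions = ["up", "down"] if direction == "both" else [direction]
    rows = []
    for ct_a, ct_b in cell_type_map.items():
        sub_a = de_a[de_a["cell_type"] == ct_a]
        sub_b = de_b[de_b["cell_type"] == ct_b]
        if len(sub_a) == 0 or len(sub_b) == 0:
            warnings.warn(f"cell types {ct_a!r}/{ct_b!r} missing from a signature; skipped")
            continue
        tested_a = set(sub_a["gene_id"])
        bg = tested_a if background == "discovery" else tested_a & set(sub_b["gene_id"])
        sub_b = sub_b[sub_b["gene_id"].isin(bg)]
        hits_a = _de_sets(sub_a, threshold_a, select_a)
        hits_b = _de_sets(sub_b, threshold_b, select_b)
        for sign_label, sgn in [(d, 1 if d == "up" else -1) for d in directions]:
            set_a = set(hits_a.loc[hits_a["direction"] == sgn, "gene_id"])
            set_b = set(hits_b.loc[hits_b["direction"] == sgn, "gene_id"])
            res = fisher_overlap(set_a, set_b, bg)
            rho, p_rho, conc = effect_concordance(
                hits_a.set_index("gene_id")["estimate"],
                hits_b.set_index("gene_id")["estimate"],
            )
            rows.append(
                {
                    "cell_type_a": ct_a,
                    "cell_type_b": ct_b,
                    "direction": sign_label,
                    "set_a_size": res.set_a_size,
                    "set_b_size": res.set_b_size,
                    "background_size": res.background_size,
                    "n_overlap": res.n_overlap,
                    "overlap_index": res.overlap_index,
                    "odds_ratio": res.odds_ratio,
                    "fisher_p": res.fisher_p,
                    "spearman_rho": rho,
                    "spearman_p": p_rho,
                    "concordance_pct": conc,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["fisher_p"].to_numpy())
    return out
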