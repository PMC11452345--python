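"""Compare two DE signatures: overlap statistics and an RRHO map.

The overlap index O(A,B) = (|A∩B|/|A| + |A∩B|/|B|)/2 weighs both sets
equally; Fisher tests score the overlap against the tested-gene background;
and the rank-rank hypergeometric overlap map scans all rank thresholds of
two signed rankings, showing where concordance (or discordance) lives.
"""

import numpy as np
import pandas as pd

from ctaging import compare_signatures, overlap_index, ranking_metric, replication_eligibility, rrho_map

rng = np.random.default_rng(5)
genes = [f"g{i}" for i in range(1500)]


def signature(de_genes, signs, seed):
    r = np.random.default_rng(seed)
    est = r.normal(0, 0.003, len(genes))
    fdr = r.uniform(0.2, 1, len(genes))
    pos = {g: i for i, g in enumerate(genes)}
    for g, s in zip(de_genes, signs):
        est[pos[g]] = s * r.uniform(0.01, 0.05)
        fdr[pos[g]] = r.uniform(0, 0.04)
    return pd.DataFrame({"gene_id": genes, "cell_type": "astro", "estimate": est,
                         "p_value": fdr / 2, "fdr": fdr, "direction": np.sign(est).astype(int)})


de_a_genes = list(rng.choice(genes, 120, replace=False))
signs = rng.choice([-1, 1], 120)
shared = rng.choice(120, 60, replace=False)  # half the signature replicates
sig_a = signature(de_a_genes, signs, seed=11)
sig_b = signature([de_a_genes[i] for i in shared], signs[shared], seed=12)

print(f"overlap index of the two DE gene sets: "
      f"{overlap_index(set(sig_a[sig_a.fdr < .05].gene_id), set(sig_b[sig_b.fdr < .05].gene_id)):.3f}")

res = compare_signatures(sig_a, sig_b, direction="both")
print("\nper-direction Fisher overlap against the 1,500-gene tested background:")
print(res[["direction", "n_overlap", "overlap_index", "odds_ratio", "fisher_p", "fdr",
           "concordance_pct"]].to_string(index=False))
print("(low FDR = the replication signature shares far more genes than chance;"
      " concordance_pct = % of shared genes moving the same way)")

eligible = replication_eligibility(sig_b["p_value"])
print(f"\n15th-percentile eligibility rule for the replication set: {'eligible' if eligible else 'ineligible'}")

rmap = rrho_map(ranking_metric(sig_a), ranking_metric(sig_b))
print(f"\nRRHO grid {rmap.grid.shape}, peak concordant signal "
      f"(-log10 hypergeometric p) = {rmap.grid.max():.1f}")
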