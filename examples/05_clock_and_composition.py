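"""Transcriptomic age, disease acceleration, and cell-composition trends.

A weighted gene panel scored on the full pseudobulk gives each donor a raw
transcriptomic age; calibration rescales it to years; the residual after
regressing out chronological age and batch is the donor's age acceleration,
tested for a disease-group offset.  Cell-type proportions are regressed on
age with the same covariates to find composition drift.
"""

import pandas as pd

from ctaging import (
    ClockPanel, SimConfig, aggregate_pseudobulk, filter_pseudobulk_genes,
    median_impute_rin, preset_params, run_clock, simulate_cohort,
)
from ctaging.composition import cell_proportions, composition_trend

cfg = SimConfig(n_donors=50, seed=13)  # plants +5y acceleration, CT_2 decline
matrix, donors, truth = simulate_cohort(cfg)
donors = median_impute_rin(donors)

full = aggregate_pseudobulk(matrix, donors, by_cell_type=False)[0]
viz = filter_pseudobulk_genes(full, **preset_params("viz"))
panel = ClockPanel(pd.Series(truth.clock_panel["weight"].to_numpy(),
                             index=truth.clock_panel["gene_id"]))
clock = run_clock(viz, panel)
row = clock.group_test.set_index("term").loc["disease_status"]
print(f"transcriptomic vs chronological age: r = {clock.age_correlation_r:.2f} "
      f"({clock.coverage[0]}/{clock.coverage[1]} panel genes matched)")
print(f"disease acceleration: {row['estimate']:+.1f} years (p = {row['p_value']:.3g}; "
      "the generator plants +5 years in disease donors)")

trend = composition_trend(cell_proportions(matrix.nuclei), donors)
print("\ncell-type proportion trends (proportion change per year of age):")
print(trend[["cell_type", "age_slope", "fdr", "significant"]].round(5).to_string(index=False))
print("(CT_2 carries the planted -0.002/year decline, the synthetic analogue of"
      " the oligodendrocyte-precursor loss seen in aging cortex)")
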