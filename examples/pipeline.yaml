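# Full-pipeline configuration: simulate a small planted cohort and run
# QC -> pseudobulk -> covariate selection -> DE -> clock -> composition.
# Run with:  ctaging run --config examples/pipeline.yaml
out_dir: pipeline_out
seed: 1
simulate:
  n_donors: 30
  n_cell_types: 4
  n_genes: 500
  de_fraction: 0.02
  burden_cell_type: CT_3
  burden_de_fraction: 0.1
  composition_slope:
    CT_2: -0.002
  clock_panel_size: 25
  nuclei_per_donor: [300.0, 0.1]
qc:
  min_counts: 200
  min_genes: 100
  min_nuclei: 50
de:
  threshold: 0.05
  disease_contrast: true
burden:
  enabled: false   # enable with >= 5000 nuclei per cell type
rrho:
  enabled: true
  min_group: 5
clock:
  enabled: true    # uses the simulated panel when no panel file is given
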