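import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ctaging import NucleusCountMatrix, SimConfig, median_impute_rin, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Hand-built 3-donor x 2-cell-type cohort with known counts.

    Gene-by-nucleus counts are chosen so per-assay pseudobulk sums can be
    verified by hand; QC metadata is attached explicitly.
    """
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(6)]
    donor_of = ["d1", "d1", "d2", "d2", "d2", "d3", "d3", "d3"]
    ct_of = ["A", "B", "A", "A", "B", "A", "B", "B"]
    counts = rng.integers(0, 20, size=(6, 8))
    nuclei = pd.DataFrame(
        {
            "nucleus_id": [f"n{i}" for i in range(8)],
            "donor_id": donor_of,
            "cell_type": ct_of,
            "pct_mito": [1.0, 2.0, 3.0, 14.9, 15.0, 0.5, 7.0, 2.0],
        }
    )
    m = NucleusCountMatrix(sp.csr_matrix(counts), np.array(genes, dtype=object), nuclei).with_qc_metrics()
    donors = pd.DataFrame(
        {
            "donor_id": ["d1", "d2", "d3"],
            "age": [30.0, 50.0, 70.0],
            "disease_status": [0, 1, 0],
            "sex": ["F", "M", "F"],
            "pH": [6.5, 6.6, 6.4],
            "RIN": [7.0, np.nan, 8.0],
            "PMI": [20.0, 25.0, 30.0],
            "lib_batch": ["B1", "B2", "B1"],
        }
    )
    return m, donors


@pytest.fixture(scope="session")
def small_sim():
    """A small planted cohort shared across test modules (read-only)."""
    cfg = SimConfig(
        n_donors=16,
        n_cell_types=4,
        n_genes=400,
        de_fraction=0.05,
        burden_cell_type="CT_3",
        burden_de_fraction=0.2,
        clock_panel_size=20,
        nuclei_per_donor=(250.0, 0.1),
        seed=11,
    )
    m, donors, gt = simulate_cohort(cfg)
    return cfg, m, median_impute_rin(donors), gt


@pytest.fixture(scope="session")
def planted_cohort():
    """Default-scale planted cohort used by the deeper recovery tests."""
    cfg = SimConfig(seed=5)
    m, donors, gt = simulate_cohort(cfg)
    return cfg, m, median_impute_rin(donors), gt
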