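"""Count-matrix containers, QC filters and pseudobulk aggregation.

The central objects are :class:`NucleusCountMatrix` (sparse genes x nuclei
counts plus per-nucleus metadata) and :class:`PseudobulkAssay` (genes x donors
summed counts for one cell type, or the full pseudobulk over all cell types).
Matrices are genes-as-rows, samples-as-columns everywhere; joins are by string
identifier, never positional.  Filters are stable (they preserve input order)
and idempotent, and every removal is recorded in a filter log.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "NucleusCountMatrix",
    "PseudobulkAssay",
    "DONOR_COLUMNS",
    "qc_filter_nuclei",
    "filter_genes_by_prevalence",
    "aggregate_pseudobulk",
    "filter_pseudobulk_genes",
    "preset_params",
    "median_impute_rin",
    "read_cohort",
    "write_cohort",
]

#: Required columns of a donor covariate table.
DONOR_COLUMNS = ["donor_id", "age", "disease_status", "sex", "pH", "RIN", "PMI", "lib_batch"]

#: Gene-filter presets.  ``de`` mirrors the per-cell-type pseudobulk filter
#: (counts >= 10 in 80% of retained donors, donors with < 5 nuclei dropped,
#: assay dropped below 70% donor retention); ``covsel`` is the stringent full
#: pseudobulk filter for covariate selection (10 counts in 90% of donors);
#: ``viz`` is the permissive filter used for trajectory visualization and the
#: transcriptomic clock (10 counts in 60% of donors).
_PRESETS = {
    "de": dict(min_count=10, min_prop=0.8, min_cells=5, min_sample_fraction=0.7),
    "covsel": dict(min_count=10, min_prop=0.9, min_cells=0, min_sample_fraction=0.0),
    "viz": dict(min_count=10, min_prop=0.6, min_cells=0, min_sample_fraction=0.0),
}


def preset_params(name: str) -> dict:
    """Return the gene-filter parameter set for a named preset."""
    try:
        return dict(_PRESETS[name])
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None


@dataclass
class NucleusCountMatrix:
    """Sparse genes x nuclei count matrix with per-nucleus metadata.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes as rows, nuclei as columns.
    gene_ids
        Unique gene identifiers, one per row.
    nuclei
        Per-nucleus metadata with at least ``donor_id`` and ``cell_type``
        columns; QC uses ``total_counts``, ``n_genes_detected`` and
        ``pct_mito`` when present.  One row per matrix column.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    nuclei: pd.DataFrame
    filter_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length does not match matrix rows")
        if self.counts.shape[1] != len(self.nuclei):
            raise ValueError("nucleus metadata rows do not match matrix columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[1]

    def with_qc_metrics(self) -> "NucleusCountMatrix":
        """Return a copy whose metadata carries ``total_counts`` and
        ``n_genes_detected`` computed from the matrix.  ``pct_mito`` is taken
        from the existing metadata (set to 0 when absent): mitochondrial gene
        annotation is outside this package's scope."""
        meta = self.nuclei.copy()
        csc = self.counts.tocsc()
        meta["total_counts"] = np.asarray(csc.sum(axis=0)).ravel().astype(int)
        meta["n_genes_detected"] = np.diff(csc.indptr)
        if "pct_mito" not in meta.columns:
            meta["pct_mito"] = 0.0
        return NucleusCountMatrix(self.counts, self.gene_ids, meta, list(self.filter_log))

    def subset_nuclei(self, mask: np.ndarray, log_entry: dict | None = None) -> "NucleusCountMatrix":
        mask = np.asarray(mask)
        log = list(self.filter_log) + ([log_entry] if log_entry else [])
        return NucleusCountMatrix(
            self.counts[:, mask].tocsr(),
            self.gene_ids,
            self.nuclei.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask].reset_index(drop=True),
            log,
        )

    def subset_genes(self, mask: np.ndarray, log_entry: dict | None = None) -> "NucleusCountMatrix":
        mask = np.asarray(mask)
        log = list(self.filter_log) + ([log_entry] if log_entry else [])
        return NucleusCountMatrix(self.counts[mask, :].tocsr(), self.gene_ids[mask], self.nuclei, log)


@dataclass
class PseudobulkAssay:
    """Genes x donors summed counts for one cell type (or the full pseudobulk).

    ``counts`` is an integer DataFrame indexed by gene id with donor ids as
    columns; ``donors`` holds the covariate rows for exactly those donors, in
    column order.  ``nuclei_contributed`` records how many nuclei each donor
    contributed to the sum, and ``norm_factors`` (when set) are TMM-style
    positive per-donor scaling factors.
    """

    cell_type: str | None
    counts: pd.DataFrame
    donors: pd.DataFrame
    nuclei_contributed: pd.Series
    norm_factors: pd.Series | None = None
    filter_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.donors["donor_id"]):
            raise ValueError("assay donor columns do not match donor table order")
        if self.norm_factors is not None and (self.norm_factors <= 0).any():
            raise ValueError("norm_factors must be positive")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_donors(self) -> int:
        return self.counts.shape[1]

    def replace(self, **kw) -> "PseudobulkAssay":
        return dataclasses.replace(self, **kw)


def median_impute_rin(donors: pd.DataFrame) -> pd.DataFrame:
    """Impute missing RIN values with the cohort median (in place on a copy)."""
    donors = donors.copy()
    if donors["RIN"].isna().any():
        donors["RIN"] = donors["RIN"].fillna(donors["RIN"].median())
    return donors


def qc_filter_nuclei(
    m: NucleusCountMatrix,
    min_counts: int = 500,
    min_genes: int = 300,
    max_pct_mito: float = 15.0,
) -> NucleusCountMatrix:
    """Remove low-quality nuclei.

    A nucleus is retained iff ``total_counts >= min_counts`` and
    ``n_genes_detected >= min_genes`` and ``pct_mito < max_pct_mito`` (the
    mitochondrial bound is exclusive).  Removals are appended to the filter
    log with per-rule counts.
    """
    for col in ("total_counts", "n_genes_detected", "pct_mito"):
        if col not in m.nuclei.columns:
            raise ValueError(f"nucleus metadata is missing required QC column {col!r}")
    if m.n_nuclei == 0:
        return m
    meta = m.nuclei
    ok_counts = meta["total_counts"].to_numpy() >= min_counts
    ok_genes = meta["n_genes_detected"].to_numpy() >= min_genes
    ok_mito = meta["pct_mito"].to_numpy() < max_pct_mito
    keep = ok_counts & ok_genes & ok_mito
    entry = {
        "step": "qc_filter_nuclei",
        "removed": int((~keep).sum()),
        "low_counts": int((~ok_counts).sum()),
        "low_genes": int((~ok_genes).sum()),
        "high_mito": int((~ok_mito).sum()),
        "params": dict(min_counts=min_counts, min_genes=min_genes, max_pct_mito=max_pct_mito),
    }
    return m.subset_nuclei(keep, entry)


def filter_genes_by_prevalence(m: NucleusCountMatrix, min_nuclei: int = 500) -> NucleusCountMatrix:
    """Keep genes detected (nonzero) in at least ``min_nuclei`` nuclei."""
    prevalence = np.diff(m.counts.tocsr().indptr)
    keep = prevalence >= min_nuclei
    entry = {
        "step": "filter_genes_by_prevalence",
        "removed": int((~keep).sum()),
        "params": dict(min_nuclei=min_nuclei),
    }
    return m.subset_genes(keep, entry)


def aggregate_pseudobulk(
    m: NucleusCountMatrix,
    donors: pd.DataFrame,
    by_cell_type: bool = True,
) -> list[PseudobulkAssay]:
    """Sum nucleus counts into per-donor pseudobulk profiles.

    With ``by_cell_type`` one assay is returned per cell type (in first-seen
    order of the metadata); otherwise a single *full pseudobulk* assay sums
    over all cell types.  Aggregation is exact integer arithmetic, so the
    total pseudobulk count equals the total retained nucleus count.
    """
    unknown = sorted(set(m.nuclei["donor_id"]) - set(donors["donor_id"]))
    if unknown:
        raise ValueError(f"nuclei reference donors absent from the donor table: {unknown}")
    donor_ids = list(donors["donor_id"])
    donor_pos = {d: i for i, d in enumerate(donor_ids)}
    col_donor = m.nuclei["donor_id"].map(donor_pos).to_numpy()

    def _sum(mask: np.ndarray, cell_type: str | None) -> PseudobulkAssay:
        idx = np.flatnonzero(mask)
        # indicator matrix nuclei -> donors keeps the sum sparse and exact
        ind = sp.csr_matrix(
            (np.ones(len(idx), dtype=np.int64), (np.arange(len(idx)), col_donor[idx])),
            shape=(len(idx), len(donor_ids)),
        )
        agg = (m.counts[:, idx] @ ind).toarray().astype(np.int64)
        contributed = np.bincount(col_donor[idx], minlength=len(donor_ids))
        return PseudobulkAssay(
            cell_type=cell_type,
            counts=pd.DataFrame(agg, index=pd.Index(m.gene_ids, name="gene_id"), columns=donor_ids),
            donors=donors.reset_index(drop=True),
            nuclei_contributed=pd.Series(contributed, index=donor_ids, name="nuclei"),
            filter_log=list(m.filter_log),
        )

    if not by_cell_type:
        return [_sum(np.ones(m.n_nuclei, dtype=bool), None)]
    cell_types = list(dict.fromkeys(m.nuclei["cell_type"]))
    ct_arr = m.nuclei["cell_type"].to_numpy()
    return [_sum(ct_arr == ct, ct) for ct in cell_types]


def filter_pseudobulk_genes(
    a: PseudobulkAssay,
    min_count: int = 10,
    min_prop: float = 0.8,
    min_cells: int = 5,
    min_sample_fraction: float = 0.7,
) -> PseudobulkAssay | None:
    """Apply the pseudobulk donor/gene filter cascade.

    Donors contributing fewer than ``min_cells`` nuclei to the assay's cell
    type are dropped.  If the retained donors fall below ``min_sample_fraction``
    of the cohort the whole assay is dropped (``None`` is returned, with the
    reason recorded on the input's log).  Surviving genes must have at least
    ``min_count`` counts in at least ``min_prop`` of the retained donors.
    """
    if not 0 < min_prop <= 1:
        raise ValueError(f"min_prop must be in (0, 1], got {min_prop}")
    n_cohort = a.n_donors
    keep_donors = (a.nuclei_contributed >= min_cells).to_numpy()
    dropped_donors = [d for d, k in zip(a.counts.columns, keep_donors) if not k]
    if keep_donors.sum() < min_sample_fraction * n_cohort:
        a.filter_log.append(
            {
                "step": "filter_pseudobulk_genes",
                "assay_dropped": True,
                "cell_type": a.cell_type,
                "retained_donors": int(keep_donors.sum()),
                "required": min_sample_fraction * n_cohort,
            }
        )
        return None
    counts = a.counts.loc[:, keep_donors]
    ok = (counts.to_numpy() >= min_count).mean(axis=1) >= min_prop
    entry = {
        "step": "filter_pseudobulk_genes",
        "cell_type": a.cell_type,
        "donors_dropped": dropped_donors,
        "genes_removed": int((~ok).sum()),
        "params": dict(
            min_count=min_count, min_prop=min_prop, min_cells=min_cells, min_sample_fraction=min_sample_fraction
        ),
    }
    return PseudobulkAssay(
        cell_type=a.cell_type,
        counts=counts.loc[ok],
        donors=a.donors.loc[keep_donors.nonzero()[0]].reset_index(drop=True)
        if not keep_donors.all()
        else a.donors,
        nuclei_contributed=a.nuclei_contributed[keep_donors],
        norm_factors=None,
        filter_log=list(a.filter_log) + [entry],
    )


# ---------------------------------------------------------------------------
# on-disk format: Matrix Market counts + TSV metadata


def write_cohort(
    m: NucleusCountMatrix,
    donors: pd.DataFrame,
    directory: str | Path,
    ground_truth=None,
) -> dict:
    """Write a cohort as Matrix Market counts plus TSV metadata files.

    Returns the mapping of logical names to file paths.  The layout round
    trips losslessly through :func:`read_cohort`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.mtx",
        "genes": directory / "genes.tsv",
        "nuclei": directory / "nuclei.tsv",
        "donors": directory / "donors.tsv",
    }
    mmwrite(paths["counts"], m.counts.astype(np.int64), field="integer")
    pd.Series(m.gene_ids, name="gene_id").to_csv(paths["genes"], sep="\t", index=False)
    m.nuclei.to_csv(paths["nuclei"], sep="\t", index=False)
    donors.to_csv(paths["donors"], sep="\t", index=False)
    if ground_truth is not None:
        paths["ground_truth"] = directory / "ground_truth.tsv"
        ground_truth.gene_effects.to_csv(paths["ground_truth"], sep="\t", index=False)
        paths["ground_truth_donors"] = directory / "ground_truth_donors.tsv"
        ground_truth.donor_effects.to_csv(paths["ground_truth_donors"], sep="\t", index=False)
        paths["ground_truth_composition"] = directory / "ground_truth_composition.tsv"
        ground_truth.composition_slopes.to_csv(paths["ground_truth_composition"], sep="\t", index=False)
    return paths


def read_cohort(directory: str | Path) -> tuple[NucleusCountMatrix, pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    counts = sp.csr_matrix(mmread(directory / "counts.mtx")).astype(np.int64)
    genes = pd.read_csv(directory / "genes.tsv", sep="\t")["gene_id"].astype(str).to_numpy()
    nuclei = pd.read_csv(
        directory / "nuclei.tsv", sep="\t", dtype={"nucleus_id": str, "donor_id": str, "cell_type": str}
    )
    if len(nuclei) == 0:  # empty cohort: pandas cannot know the column dtypes
        counts = sp.csr_matrix((len(genes), 0), dtype=np.int64)
    donors = pd.read_csv(directory / "donors.tsv", sep="\t", dtype={"donor_id": str, "lib_batch": str})
    m = NucleusCountMatrix(counts, genes, nuclei)
    return m, donors
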