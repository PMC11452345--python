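"""Synthetic single-nucleus aging cohort with planted ground truth.

Emulates the statistical structure of a postmortem single-nucleus RNA-seq
aging cohort: donors spanning a configurable age range with psychiatric-case
status and technical covariates (pH, RIN, PMI, library batch), a handful of
cell types whose per-donor nucleus counts follow a Dirichlet-multinomial with
optional per-year composition drift, and negative-binomial nucleus counts
whose log2 means move linearly with age and disease for a planted subset of
genes per cell type.  One cell type may carry an elevated fraction of
age-regulated genes (the "burden" cell type), one cell type's proportion may
decline with age, and a clock gene panel carries a coordinated age signal
that is shifted by a configurable number of years in disease donors.

All randomness flows from a single root seed through named
``numpy.random.SeedSequence`` substreams (donors, effects, composition,
counts), so a fixed seed yields bit-identical cohorts and individual
components are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import NucleusCountMatrix, write_cohort

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "write_fixture"]


def _as_fraction(name: str, value: float) -> float:
    if not 0 <= value <= 1:
        raise ValueError(f"{name} must be in [0, 1], got {value}")
    return float(value)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a desk-scale cohort: 40 donors aged 26-84, 8 cell
    types, 2,000 genes, ~600 nuclei per donor, a baseline 1% of genes
    age-regulated per cell type with one cell type elevated tenfold, 60% of
    age-regulated genes downregulated, and a +5-year transcriptomic-age
    acceleration in disease donors injected through a 50-gene clock panel.
    """

    n_donors: int = 40
    age_range: tuple[float, float] = (26.0, 84.0)
    disease_prob: float = 0.4
    n_cell_types: int = 8
    cell_type_base_proportions: np.ndarray | None = None
    #: proportion change per year, keyed by cell type; the default single
    #: negative entry emulates the observed OPC decline with age
    composition_slope: dict = field(default_factory=lambda: {"CT_2": -0.002})
    n_genes: int = 2000
    #: fraction of genes age-regulated per cell type (scalar or per-type map)
    de_fraction: float | dict = 0.01
    burden_cell_type: str | None = "CT_3"
    burden_de_fraction: float = 0.10
    down_fraction: float = 0.6
    #: |age slope| is drawn uniformly from this range (log2 units per year)
    age_effect_scale: tuple[float, float] = (0.005, 0.05)
    disease_effect_fraction: float = 0.02
    disease_effect_scale: tuple[float, float] = (0.05, 0.3)
    clock_panel_size: int = 50
    clock_acceleration_years: float = 5.0
    #: log2 units per effective year per unit of panel weight
    clock_effect_scale: float = 0.02
    #: mean nuclei per donor and its coefficient of variation
    nuclei_per_donor: tuple[float, float] = (600.0, 0.15)
    nb_dispersion: float = 0.3
    n_batches: int = 2
    batch_effect_scale: float = 0.1
    #: Dirichlet-multinomial concentration of per-donor cell-type mixing
    dm_concentration: float = 300.0
    #: mean per-nucleus sequencing depth and log-scale sd
    depth: tuple[float, float] = (2000.0, 0.3)
    #: leave one donor's RIN missing to exercise median imputation
    rin_missing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 4:
            raise ValueError(f"n_donors must be >= 4, got {self.n_donors}")
        _as_fraction("disease_prob", self.disease_prob)
        _as_fraction("down_fraction", self.down_fraction)
        _as_fraction("disease_effect_fraction", self.disease_effect_fraction)
        _as_fraction("burden_de_fraction", self.burden_de_fraction)
        if self.nb_dispersion < 0:
            raise ValueError(f"nb_dispersion must be non-negative, got {self.nb_dispersion}")
        if self.dm_concentration <= 0:
            raise ValueError(f"dm_concentration must be positive, got {self.dm_concentration}")
        if self.cell_type_base_proportions is None:
            # mildly uneven abundances, most mass on the first few types
            w = np.linspace(1.8, 0.6, self.n_cell_types)
            self.cell_type_base_proportions = w / w.sum()
        p = np.asarray(self.cell_type_base_proportions, dtype=float)
        if len(p) != self.n_cell_types or abs(p.sum() - 1.0) > 1e-12 or (p <= 0).any():
            raise ValueError(
                "cell_type_base_proportions must be a positive vector of length "
                f"n_cell_types summing to 1, got {p!r}"
            )
        self.cell_type_base_proportions = p
        known = set(self.cell_types)
        for ct in self.composition_slope:
            if ct not in known:
                raise ValueError(f"composition_slope names unknown cell type {ct!r}")
        for ct, frac in self.de_fraction_map().items():
            _as_fraction(f"de_fraction[{ct}]", frac)

    @property
    def cell_types(self) -> list[str]:
        return [f"CT_{i + 1}" for i in range(self.n_cell_types)]

    def de_fraction_map(self) -> dict:
        cts = self.cell_types
        if isinstance(self.de_fraction, dict):
            frac = {ct: float(self.de_fraction.get(ct, 0.0)) for ct in cts}
        else:
            frac = {ct: float(self.de_fraction) for ct in cts}
        if self.burden_cell_type is not None:
            if self.burden_cell_type not in frac:
                raise ValueError(f"burden_cell_type {self.burden_cell_type!r} is not a cell type")
            if not isinstance(self.de_fraction, dict):
                frac[self.burden_cell_type] = self.burden_de_fraction
        return frac

    @classmethod
    def null(cls, **overrides) -> "SimConfig":
        """A cohort with no planted effects of any kind (a null experiment)."""
        base = dict(
            de_fraction=0.0,
            burden_cell_type=None,
            disease_effect_fraction=0.0,
            batch_effect_scale=0.0,
            clock_panel_size=0,
            composition_slope={},
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """Planted parameters of a simulated cohort.

    ``gene_effects`` has one row per (gene, cell type) with the true age
    slope (log2 per year), the ``is_de`` flag, the direction (sign of the
    slope) and the true disease effect (log2 units).  ``donor_effects``
    records each donor's planted transcriptomic-age offset in years, and
    ``composition_slopes`` the per-year proportion drift of each cell type.
    ``clock_panel`` lists the panel genes with their score weights.
    """

    gene_effects: pd.DataFrame
    donor_effects: pd.DataFrame
    composition_slopes: pd.DataFrame
    clock_panel: pd.DataFrame

    def de_genes(self, cell_type: str) -> pd.DataFrame:
        g = self.gene_effects
        return g[(g["cell_type"] == cell_type) & g["is_de"]]


def _simulate_donors(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_donors
    lo, hi = cfg.age_range
    donors = pd.DataFrame(
        {
            "donor_id": [f"D{i + 1:03d}" for i in range(n)],
            "age": np.round(rng.uniform(lo, hi, n), 1),
            "disease_status": (rng.random(n) < cfg.disease_prob).astype(int),
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
            "pH": np.round(rng.normal(6.5, 0.25, n), 2),
            "RIN": np.round(np.clip(rng.normal(7.5, 1.0, n), 5.0, 10.0), 1),
            "PMI": np.round(np.clip(rng.normal(30.0, 10.0, n), 4.0, None), 1),
            "lib_batch": [f"B{b + 1}" for b in rng.integers(0, cfg.n_batches, n)],
        }
    )
    # guarantee both groups and both batch levels are populated
    if donors["disease_status"].nunique() == 1:
        donors.loc[donors.index[:2], "disease_status"] = [0, 1]
    if cfg.n_batches > 1 and donors["lib_batch"].nunique() == 1:
        donors.loc[donors.index[0], "lib_batch"] = "B2" if donors["lib_batch"].iloc[0] == "B1" else "B1"
    if cfg.rin_missing:
        donors.loc[donors.index[rng.integers(n)], "RIN"] = np.nan
    return donors


def _plant_effects(cfg: SimConfig, rng: np.random.Generator):
    """Draw per-(gene, cell type) age and disease effects plus the clock panel."""
    n_g, cts = cfg.n_genes, cfg.cell_types
    age_slope = np.zeros((len(cts), n_g))
    disease_eff = np.zeros((len(cts), n_g))
    is_de = np.zeros((len(cts), n_g), dtype=bool)

    panel_size = min(cfg.clock_panel_size, n_g)
    panel_idx = rng.choice(n_g, size=panel_size, replace=False)
    panel_idx.sort()
    panel_w = rng.normal(0.0, 1.0, panel_size)
    panel_w[np.abs(panel_w) < 0.2] += np.sign(panel_w[np.abs(panel_w) < 0.2] + 1e-12) * 0.2

    non_panel = np.setdiff1d(np.arange(n_g), panel_idx)
    lo_b, hi_b = cfg.age_effect_scale
    frac_map = cfg.de_fraction_map()
    for i, ct in enumerate(cts):
        n_de = int(np.floor(frac_map[ct] * n_g))
        idx = rng.choice(non_panel, size=min(n_de, len(non_panel)), replace=False)
        mag = rng.uniform(lo_b, hi_b, len(idx))
        n_down = int(round(cfg.down_fraction * len(idx)))
        sign = np.ones(len(idx))
        sign[:n_down] = -1.0  # exact down fraction: flags assigned, not sampled
        age_slope[i, idx] = sign * mag
        is_de[i, idx] = True

        n_dis = int(np.floor(cfg.disease_effect_fraction * n_g))
        didx = rng.choice(n_g, size=n_dis, replace=False)
        dmag = rng.uniform(*cfg.disease_effect_scale, n_dis)
        dsign = np.where(rng.random(n_dis) < 0.5, -1.0, 1.0)
        disease_eff[i, didx] += dsign * dmag

    # clock panel: coordinated age signal, shifted by the planted acceleration
    # in disease donors; applies to every cell type (the clock reads the full
    # pseudobulk), so panel genes are genuinely age-regulated everywhere
    gamma = cfg.clock_effect_scale * panel_w
    age_slope[:, panel_idx] += gamma
    disease_eff[:, panel_idx] += gamma * cfg.clock_acceleration_years
    if panel_size and cfg.clock_effect_scale != 0:
        is_de[:, panel_idx] = True
    return age_slope, disease_eff, is_de, panel_idx, panel_w


def _donor_proportions(cfg: SimConfig, ages: np.ndarray) -> np.ndarray:
    """Per-donor expected cell-type proportions with logit-scale age drift."""
    p0 = cfg.cell_type_base_proportions
    if len(p0) == 1:
        return np.ones((len(ages), 1))
    slopes = np.array([cfg.composition_slope.get(ct, 0.0) for ct in cfg.cell_types])
    mid = np.mean(cfg.age_range)
    logit0 = np.log(p0 / (1 - p0))
    # proportion slope on the logit scale (d logit/dp = 1/(p(1-p))), with an
    # extra 1/(1-p) compensating the renormalization so the realized marginal
    # slope of a drifting cell type matches the configured value
    logit_slope = slopes / (p0 * (1 - p0) ** 2)
    l = logit0[None, :] + logit_slope[None, :] * (ages[:, None] - mid)
    p = 1.0 / (1.0 + np.exp(-l))
    return p / p.sum(axis=1, keepdims=True)


def simulate_cohort(config: SimConfig) -> tuple[NucleusCountMatrix, pd.DataFrame, GroundTruth]:
    """Generate a cohort: nucleus counts, donor covariates and ground truth.

    Returns a :class:`~ctaging.io.NucleusCountMatrix` (with QC metadata
    columns populated), a donor covariate table and a :class:`GroundTruth`.
    """
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_donors, rng_effects, rng_comp, rng_counts = (np.random.default_rng(s) for s in streams)

    donors = _simulate_donors(cfg, rng_donors)
    age_slope, disease_eff, is_de, panel_idx, panel_w = _plant_effects(cfg, rng_effects)

    ages = donors["age"].to_numpy(float)
    mid = np.mean(cfg.age_range)
    disease = donors["disease_status"].to_numpy()
    batches = sorted(donors["lib_batch"].unique())
    batch_of = donors["lib_batch"].map({b: i for i, b in enumerate(batches)}).to_numpy()
    batch_eff = rng_effects.normal(0.0, cfg.batch_effect_scale, (len(batches), cfg.n_genes)) if cfg.batch_effect_scale > 0 else np.zeros((len(batches), cfg.n_genes))

    # per-donor nucleus allocation across cell types (Dirichlet-multinomial)
    props = _donor_proportions(cfg, ages)
    mean_n, cv = cfg.nuclei_per_donor
    if cv > 0:
        totals = rng_comp.poisson(rng_comp.gamma(1.0 / cv**2, mean_n * cv**2, cfg.n_donors))
    else:
        totals = np.full(cfg.n_donors, int(round(mean_n)))
    totals = np.maximum(totals, cfg.n_cell_types)
    alloc = np.empty((cfg.n_donors, cfg.n_cell_types), dtype=int)
    for d in range(cfg.n_donors):
        theta = rng_comp.dirichlet(props[d] * cfg.dm_concentration)
        alloc[d] = rng_comp.multinomial(totals[d], theta)

    base_log2 = rng_effects.normal(0.0, 1.5, cfg.n_genes)
    ct_offset = rng_effects.normal(0.0, 0.3, (cfg.n_cell_types, cfg.n_genes))

    depth_mean, depth_sd = cfg.depth
    r0 = 1.0 / cfg.nb_dispersion if cfg.nb_dispersion > 0 else None
    gene_ids = np.array([f"G{i + 1:05d}" for i in range(cfg.n_genes)], dtype=object)

    blocks, meta_rows = [], []
    for d in range(cfg.n_donors):
        eff_age = ages[d] - mid
        for c, ct in enumerate(cfg.cell_types):
            k = alloc[d, c]
            if k == 0:
                continue
            log2mu = (
                base_log2
                + ct_offset[c]
                + age_slope[c] * eff_age
                + disease_eff[c] * disease[d]
                + batch_eff[batch_of[d]]
            )
            rel = np.exp2(log2mu)
            rel /= rel.sum()
            depths = rng_counts.lognormal(np.log(depth_mean), depth_sd, k)
            mu = rel[:, None] * depths[None, :]
            if r0 is not None:
                counts = rng_counts.negative_binomial(r0, r0 / (r0 + mu))
            else:
                counts = rng_counts.poisson(mu)
            blocks.append(sp.csr_matrix(counts.astype(np.int64)))
            pct_mito = np.round(rng_counts.gamma(2.0, 2.5, k), 2)
            did = donors["donor_id"].iloc[d]
            meta_rows.append(
                pd.DataFrame(
                    {
                        "nucleus_id": [f"{did}_{ct}_{j}" for j in range(k)],
                        "donor_id": did,
                        "cell_type": ct,
                        "pct_mito": pct_mito,
                    }
                )
            )

    if blocks:
        counts = sp.hstack(blocks, format="csr")
        nuclei = pd.concat(meta_rows, ignore_index=True)
    else:
        counts = sp.csr_matrix((cfg.n_genes, 0), dtype=np.int64)
        nuclei = pd.DataFrame(columns=["nucleus_id", "donor_id", "cell_type", "pct_mito"])
    m = NucleusCountMatrix(counts, gene_ids, nuclei).with_qc_metrics()

    gene_effects = pd.DataFrame(
        {
            "gene_id": np.tile(gene_ids, cfg.n_cell_types),
            "cell_type": np.repeat(cfg.cell_types, cfg.n_genes),
            "age_slope": age_slope.ravel(),
            "is_de": is_de.ravel(),
            "direction": np.sign(age_slope.ravel()).astype(int),
            "disease_effect": disease_eff.ravel(),
        }
    )
    gt = GroundTruth(
        gene_effects=gene_effects,
        donor_effects=pd.DataFrame(
            {
                "donor_id": donors["donor_id"],
                "clock_offset_years": disease * float(cfg.clock_acceleration_years if len(panel_idx) else 0.0),
            }
        ),
        composition_slopes=pd.DataFrame(
            {
                "cell_type": cfg.cell_types,
                "slope_per_year": [cfg.composition_slope.get(ct, 0.0) for ct in cfg.cell_types],
            }
        ),
        clock_panel=pd.DataFrame({"gene_id": gene_ids[panel_idx], "weight": panel_w}),
    )
    return m, donors, gt


def write_fixture(
    cohort: tuple[NucleusCountMatrix, pd.DataFrame, GroundTruth],
    directory: str | Path,
) -> dict:
    """Write a simulated cohort to ``directory`` (Matrix Market + TSV files).

    The layout round-trips losslessly through :func:`ctaging.io.read_cohort`.
    """
    m, donors, gt = cohort
    paths = write_cohort(m, donors, directory, ground_truth=gt)
    panel_path = Path(directory) / "clock_panel.tsv"
    gt.clock_panel.to_csv(panel_path, sep="\t", index=False)
    paths["clock_panel"] = panel_path
    return paths
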