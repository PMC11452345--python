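"""End-to-end orchestration of the cell-type aging analysis.

A single :class:`RunConfig` (typically loaded from YAML) drives the full
chain: simulate or load a cohort, nucleus/gene QC, pseudobulk aggregation,
covariate selection (hidden-confounder PC1), per-cell-type age differential
expression, optional disease contrast and convergence overlap, the
downsampling burden ranking, an RRHO comparison of the neurotypical and
disease subcohorts' aging signatures, the transcriptomic clock, and
cell-composition trends.  Every stage validates its parameters before any
stage runs, writes plain TSV/Matrix Market/JSON outputs, and appends a
manifest entry with parameters and output checksums, so a rerun with the
same config and seed is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import composition as comp_mod
from .clock import ClockPanel, run_clock
from .covariates import associate_covariates, hidden_confounder_pc1, stabilize_and_pca
from .diffexpr import DesignSpec, run_de
from .io import (
    aggregate_pseudobulk,
    filter_genes_by_prevalence,
    filter_pseudobulk_genes,
    median_impute_rin,
    preset_params,
    qc_filter_nuclei,
    read_cohort,
    write_cohort,
)
from .overlap import compare_signatures
from .rrho import ranking_metric, rrho_map
from .simulate import SimConfig, simulate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable record."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage {stage!r} failed: {error}")
        self.stage = stage
        self.record = {"stage": stage, "error": type(error).__name__, "message": str(error)}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str
    seed: int = 0
    input_dir: str | None = None  # cohort fixture directory; None -> simulate
    simulate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)  # min_counts, min_genes, max_pct_mito, min_nuclei
    de: dict = field(default_factory=dict)  # threshold, disease contrast toggle
    burden: dict = field(default_factory=dict)  # enabled, n_nuclei, n_reps
    rrho: dict = field(default_factory=dict)  # enabled, min_group
    clock: dict = field(default_factory=dict)  # enabled, panel path
    composition: dict = field(default_factory=dict)
    n_pcs: int = 10

    def __post_init__(self) -> None:
        # fail fast: every block must validate before any stage runs
        if self.input_dir is None:
            self._sim_config = SimConfig(**{**self.simulate, "seed": self.simulate.get("seed", self.seed)})
        else:
            self._sim_config = None
        qc_keys = {"min_counts", "min_genes", "max_pct_mito", "min_nuclei"}
        unknown = set(self.qc) - qc_keys
        if unknown:
            raise ValueError(f"unknown qc parameters: {sorted(unknown)}")
        thr = self.de.get("threshold", 0.05)
        if not 0 < thr < 1:
            raise ValueError(f"de.threshold must be in (0,1), got {thr}")
        self._age_spec = DesignSpec(contrast="age", de_threshold=thr)
        if self.burden.get("enabled", False):
            if self.burden.get("n_reps", 10) < 2:
                raise ValueError("burden.n_reps must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages in dependency order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}

    def record(stage: str, t0: float, params: dict, files: dict) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "wall_time_s": round(time.time() - t0, 3),
                "params": params,
                "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))} for k, p in files.items()},
            }
        )

    def stage(name):
        def deco(fn):
            def wrapped(*a, **kw):
                t0 = time.time()
                try:
                    return fn(t0, *a, **kw)
                except PipelineError:
                    raise
                except Exception as e:  # noqa: BLE001 - converted to a stage record
                    err = PipelineError(name, e)
                    (out / "error.json").write_text(json.dumps(err.record, indent=2))
                    manifest_path = out / "manifest.json"
                    manifest_path.write_text(json.dumps(manifest, indent=2))
                    raise err from e
            return wrapped
        return deco

    # ------------------------------------------------------------------ input
    @stage("cohort")
    def load_cohort(t0):
        if config.input_dir is not None:
            m, donors = read_cohort(config.input_dir)
            gt = None
        else:
            m, donors, gt = simulate_cohort(config._sim_config)
        donors = median_impute_rin(donors)
        paths = write_cohort(m, donors, out / "cohort")
        record("cohort", t0, {"simulated": config.input_dir is None}, paths)
        return m, donors, gt

    m, donors, gt = load_cohort()

    @stage("qc")
    def qc(t0, m):
        qc_params = dict(config.qc)
        min_nuclei = qc_params.pop("min_nuclei", 500)
        m = qc_filter_nuclei(m, **qc_params)
        m = filter_genes_by_prevalence(m, min_nuclei=min_nuclei)
        log_path = out / "qc_filter_log.json"
        log_path.write_text(json.dumps(m.filter_log, indent=2, default=str))
        record("qc", t0, {**config.qc, "min_nuclei": min_nuclei}, {"filter_log": log_path})
        return m

    m = qc(m)

    @stage("pseudobulk")
    def pseudobulk(t0, m, donors):
        per_ct = aggregate_pseudobulk(m, donors, by_cell_type=True)
        full = aggregate_pseudobulk(m, donors, by_cell_type=False)[0]
        pb_dir = out / "pseudobulk"
        pb_dir.mkdir(exist_ok=True)
        files = {}
        for a in per_ct + [full]:
            name = a.cell_type or "full"
            p = pb_dir / f"{name}.tsv"
            a.counts.to_csv(p, sep="\t")
            files[name] = p
        record("pseudobulk", t0, {}, files)
        return per_ct, full

    per_ct, full = pseudobulk(m, donors)

    @stage("covariates")
    def covariates(t0, full, donors):
        cov_assay = filter_pseudobulk_genes(full, **preset_params("covsel"))
        n_pcs = min(config.n_pcs, cov_assay.n_genes, cov_assay.n_donors)
        _, scores, _ = stabilize_and_pca(cov_assay, n_pcs)
        report = associate_covariates(scores, donors, n_pcs)
        pc1 = hidden_confounder_pc1(cov_assay, [t for t in ["disease_status", "sex", "pH", "RIN", "PMI", "lib_batch"] if t in donors.columns])
        donors = donors.merge(pc1.rename("PC1"), left_on="donor_id", right_index=True)
        rep_path = out / "covariate_report.tsv"
        report.associations.to_csv(rep_path, sep="\t", index=False)
        don_path = out / "donors_with_pc1.tsv"
        donors.to_csv(don_path, sep="\t", index=False)
        record("covariates", t0, {"n_pcs": n_pcs, "selected": report.selected},
               {"report": rep_path, "donors": don_path})
        return donors

    donors = covariates(full, donors)

    def _refresh(assays):
        # re-attach the PC1-augmented donor table to each assay
        fresh = []
        for a in assays:
            sub = donors.set_index("donor_id").loc[list(a.counts.columns)].reset_index()
            fresh.append(a.replace(donors=sub))
        return fresh

    per_ct, full = _refresh(per_ct), _refresh([full])[0]

    @stage("de")
    def de_stage(t0, per_ct):
        filtered = [filter_pseudobulk_genes(a, **preset_params("de")) for a in per_ct]
        de = run_de([a for a in filtered if a is not None], config._age_spec)
        de_path = out / "de_age.tsv"
        de.to_csv(de_path, sep="\t", index=False)
        files = {"age": de_path}
        de_disease = None
        if config.de.get("disease_contrast", True):
            spec = DesignSpec(contrast="disease_status")
            de_disease = run_de([a for a in filtered if a is not None], spec)
            p = out / "de_disease.tsv"
            de_disease.to_csv(p, sep="\t", index=False)
            files["disease"] = p
        record("de", t0, {"threshold": config._age_spec.de_threshold}, files)
        return de, de_disease, filtered

    de_age, de_disease, filtered = de_stage(per_ct)

    if de_disease is not None and len(de_age) and len(de_disease):
        @stage("convergence")
        def convergence(t0):
            conv = compare_signatures(de_age, de_disease, threshold_b=0.1)
            p = out / "age_disease_overlap.tsv"
            conv.to_csv(p, sep="\t", index=False)
            record("convergence", t0, {}, {"overlap": p})
        convergence()

    if config.burden.get("enabled", False):
        @stage("burden")
        def burden_stage(t0, m, donors):
            res = burden_mod.downsample_and_count(
                m,
                donors,
                spec=config._age_spec,
                n_nuclei=config.burden.get("n_nuclei", 5000),
                n_reps=config.burden.get("n_reps", 10),
                seed=config.seed,
            )
            cp = out / "burden_counts.tsv"
            res.counts.to_csv(cp, sep="\t")
            pp = out / "burden_pairwise.tsv"
            files = {"counts": cp}
            if res.pairwise is not None:
                res.pairwise.to_csv(pp, sep="\t", index=False)
                files["pairwise"] = pp
            record("burden", t0, {"n_nuclei": res.n_nuclei, "n_reps": res.n_reps}, files)
        burden_stage(m, donors)

    if config.rrho.get("enabled", True):
        @stage("rrho")
        def rrho_stage(t0, per_ct, donors):
            min_group = config.rrho.get("min_group", 10)
            groups = donors.groupby("disease_status")["donor_id"].apply(list)
            if len(groups) == 2 and all(len(g) >= min_group for g in groups):
                des = []
                for status, ids in groups.items():
                    sub_assays = []
                    for a in per_ct:
                        keep = a.donors["donor_id"].isin(ids).to_numpy()
                        sub = a.replace(
                            counts=a.counts.loc[:, keep],
                            donors=a.donors[keep].reset_index(drop=True),
                            nuclei_contributed=a.nuclei_contributed[keep],
                        )
                        sub = filter_pseudobulk_genes(sub, **preset_params("de"))
                        if sub is not None:
                            sub_assays.append(sub)
                    full_terms = [
                        t for t in ["age", "sex", "pH", "RIN", "PMI", "lib_batch", "PC1"]
                        if t == "age" or t in donors.columns
                    ]
                    # small subcohorts cannot support the full design
                    terms = full_terms if len(ids) >= len(full_terms) + 6 else ["age"]
                    des.append(run_de(sub_assays, DesignSpec(contrast="age", terms=terms)))
                files = {}
                for ct in de_age["cell_type"].unique():
                    a_ct = des[0][des[0]["cell_type"] == ct]
                    b_ct = des[1][des[1]["cell_type"] == ct]
                    if len(a_ct) < 10 or len(b_ct) < 10:
                        continue
                    rmap = rrho_map(ranking_metric(a_ct), ranking_metric(b_ct))
                    p = out / f"rrho_{ct}.tsv"
                    pd.DataFrame(rmap.grid, index=rmap.thresholds, columns=rmap.thresholds).to_csv(p, sep="\t")
                    sidecar = out / f"rrho_{ct}.json"
                    sidecar.write_text(json.dumps({"step": rmap.step, "n_genes": rmap.n_genes,
                                                   "split_a": rmap.split_a, "split_b": rmap.split_b}))
                    files[ct] = p
                record("rrho", t0, {"groups": [int(s) for s in groups.index]}, files)
            else:
                record("rrho", t0, {"skipped": "a disease group is too small"}, {})
        rrho_stage(per_ct, donors)

    if config.clock.get("enabled", True):
        @stage("clock")
        def clock_stage(t0, full, gt):
            panel_path = config.clock.get("panel")
            if panel_path:
                from .clock import read_panel
                panel = read_panel(panel_path)
            elif gt is not None and len(gt.clock_panel):
                panel = ClockPanel(
                    weights=pd.Series(gt.clock_panel["weight"].to_numpy(), index=gt.clock_panel["gene_id"]),
                    provenance="simulated panel",
                )
            else:
                record("clock", t0, {"skipped": "no panel available"}, {})
                return
            viz = filter_pseudobulk_genes(full, **preset_params("viz"))
            res = run_clock(viz, panel)
            p = out / "clock.tsv"
            pd.DataFrame(
                {"donor_id": res.raw_score.index, "raw_score": res.raw_score.to_numpy(),
                 "calibrated_age": res.calibrated_age.to_numpy(), "acceleration": res.acceleration.to_numpy()}
            ).to_csv(p, sep="\t", index=False)
            files = {"clock": p}
            if res.group_test is not None:
                gp = out / "clock_group_test.tsv"
                res.group_test.to_csv(gp, sep="\t", index=False)
                files["group_test"] = gp
            record("clock", t0, {"coverage": list(res.coverage), "r": res.age_correlation_r}, files)
        clock_stage(full, gt)

    @stage("composition")
    def composition_stage(t0, m, donors):
        props = comp_mod.cell_proportions(m.nuclei)
        trend = comp_mod.composition_trend(props, donors)
        pp = out / "composition_proportions.tsv"
        props.to_csv(pp, sep="\t")
        tp = out / "composition_trend.tsv"
        trend.to_csv(tp, sep="\t", index=False)
        record("composition", t0, {}, {"proportions": pp, "trend": tp})

    composition_stage(m, donors)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
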