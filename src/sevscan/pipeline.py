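"""End-to-end orchestration: simulate -> qc -> call -> enrich -> famd -> associate.

Stages exchange plain TSV/BED/JSON files inside one output directory so
every intermediate is inspectable, and a JSON run manifest (parameters,
seeds, record counts, file checksums, durations) permits an exact re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, enrichment, famd, io, sev, synthetic
from .errors import StageError

STAGES = ["simulate", "qc", "call", "enrich", "famd", "associate"]


@dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults.

    The SEV-specific defaults: fence multiplier 3 (extreme outliers),
    detection-p threshold 0.05, 5 kb windows with 50% overlap, alpha 0.05
    with Bonferroni correction, 10 phenotype dimensions, genome-wide
    threshold 1e-7.
    """

    out_dir: str = "sevscan_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sim: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)
    # qc
    detection_threshold: float = 0.05
    max_unreliable: float = 0.0
    # calling
    fence_multiplier: float = 3.0
    quantile_method: str = "hinges"
    min_reference_n: int = 10
    internal_mode: str = "pooled"
    n_external: int = 41
    external_cord_shift_sd: float = 0.02
    whole_blood_shift_sd: float = 0.05
    # enrichment
    window: int = 5000
    step: int = 2500
    alpha: float = 0.05
    # phenotypes / association
    n_dims: int = 10
    genomewide_threshold: float = 1e-7

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = synthetic.SimulationConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **raw)
        cfg.sim.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.sim.seed = config.seed
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            records = _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:  # halt with a stage-named error
            raise StageError(stage, str(exc)) from exc
        manifest["stages"][stage] = {
            "duration_s": round(time.perf_counter() - t0, 3),
            **records,
        }
    manifest["files"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file()
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> dict:
    ann = synthetic.generate_annotation(config.sim)
    beta, detp, truth = synthetic.generate_cohort(config.sim, ann)
    pheno = synthetic.generate_phenotypes(config.sim, truth)
    io.write_beta_tsv(beta, out / "beta.tsv")
    io.write_detp_tsv(detp, out / "detp.tsv")
    io.write_annotation_tsv(ann.probes, out / "annotation.tsv")
    io.write_bed(ann.genes, out / "genes.bed")
    io.write_bed(ann.dmrs, out / "imprinted_dmrs.bed")
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index_label="sample_id")
    truth.to_json(out / "ground_truth.json")
    state.update(annotation=ann, beta=beta, detp=detp, truth=truth, pheno=pheno)
    return {"n_probes": len(beta), "n_samples": beta.shape[1]}


def _stage_qc(config: RunConfig, out: Path, state: dict) -> dict:
    beta, report = io.filter_probes(state["beta"], state["annotation"].probes)
    detp = state["detp"].loc[beta.index]
    kept_probes, kept_samples, trace = io.greedycut(
        detp, config.detection_threshold, config.max_unreliable
    )
    beta = beta.loc[kept_probes, kept_samples]
    trace.to_csv(out / "greedycut_trace.tsv", sep="\t", index=False)
    io.write_beta_tsv(beta, out / "beta_qc.tsv")
    state["beta_qc"] = beta
    state["annotation_qc"] = state["annotation"].probes.loc[kept_probes]
    return {
        "removed_by_flag": report.removed_by,
        "greedycut_removed": len(trace),
        "n_probes": len(beta),
        "n_samples": beta.shape[1],
    }


def _stage_call(config: RunConfig, out: Path, state: dict) -> dict:
    beta = state["beta_qc"]
    sim = config.sim
    truth = state["truth"]
    controls, _ = sim.sample_ids()
    internal_ref = beta[controls]
    common_means = truth.probe_means.loc[beta.index]
    ext_cord = synthetic.generate_reference_cohort(
        sim, state["annotation"], common_means, config.n_external,
        mean_shift_sd=config.external_cord_shift_sd, prefix="cord",
    )
    whole_blood = synthetic.generate_reference_cohort(
        sim, state["annotation"], common_means, config.n_external,
        mean_shift_sd=config.whole_blood_shift_sd, prefix="wb",
    )
    references = {
        "internal_pooled": internal_ref,
        "external_cord": ext_cord,
        "external_wholeblood": whole_blood,
    }
    profile = sev.sev_profile(
        beta,
        references,
        internal_mode=config.internal_mode,
        min_n=config.min_reference_n,
        multiplier=config.fence_multiplier,
        quantile_method=config.quantile_method,
    )
    profile.summary.to_csv(out / "sev_summary.tsv", sep="\t", index=False)
    calls = pd.concat(
        [
            cs.calls.assign(sample_id=cs.sample_id, mode=cs.reference_mode)
            for cs in profile.call_sets.values()
        ],
        ignore_index=True,
    )
    calls.to_csv(out / "sev_calls.tsv", sep="\t", index=False)
    state["profile"] = profile
    return {
        "n_common_probes": profile.n_common_probes,
        "total_calls": int(profile.summary["n_sev"].sum()),
    }


def _stage_enrich(config: RunConfig, out: Path, state: dict) -> dict:
    profile = state["profile"]
    ann = state["annotation_qc"]
    dmrs = state["annotation"].dmrs
    dmr_index = io.probe_region_index(ann, dmrs)
    window_reports, dmr_reports = [], []
    for (sample, mode), cs in profile.call_sets.items():
        wr = enrichment.window_enrichment(
            cs, ann, config.window, config.step, config.alpha
        )
        wr["mode"] = mode
        window_reports.append(wr)
        dr = enrichment.region_enrichment(
            cs, dmrs, dmr_index, config.alpha, N=len(ann)
        )
        dr["mode"] = mode
        dmr_reports.append(dr)
    windows = pd.concat(window_reports, ignore_index=True)
    dmr_rep = pd.concat(dmr_reports, ignore_index=True)
    counts = enrichment.enriched_region_counts(windows)
    windows[windows["enriched"]].to_csv(
        out / "enriched_windows.tsv", sep="\t", index=False
    )
    dmr_rep.to_csv(out / "dmr_enrichment.tsv", sep="\t", index=False)
    counts.to_csv(out / "enriched_window_counts.tsv", sep="\t", index=False)
    state["dmr_enrichment"] = dmr_rep
    state["enriched_counts"] = counts
    return {
        "enriched_windows": int(windows["enriched"].sum()),
        "enriched_dmrs": int(dmr_rep["enriched"].sum()),
    }


def _stage_famd(config: RunConfig, out: Path, state: dict) -> dict:
    pheno = state["pheno"].drop(columns=["case_control"])
    model = famd.famd_fit(pheno, n_dims=config.n_dims)
    corr = famd.dim_trait_correlations(model, pheno)
    group = state["pheno"]["case_control"]
    logit = famd.dims_vs_group(model, group, alpha=config.alpha)
    model.dimension_scores.to_csv(out / "famd_scores.tsv", sep="\t")
    model.variable_loadings.to_csv(out / "famd_loadings.tsv", sep="\t")
    corr.to_csv(out / "dim_trait_correlations.tsv", sep="\t", index=False)
    logit.to_csv(out / "dims_vs_group.tsv", sep="\t", index=False)
    state["model"] = model
    state["dims_vs_group"] = logit
    return {
        "n_dims": model.n_dims,
        "variance_10dims": float(
            model.cumulative_variance[min(config.n_dims, len(model.cumulative_variance)) - 1]
        ),
    }


def _stage_associate(config: RunConfig, out: Path, state: dict) -> dict:
    profile = state["profile"]
    model = state["model"]
    batch = synthetic.batch_labels(config.sim)
    log_sev = profile.log_sev_table()
    assoc = association.sev_dim_regression(
        log_sev, model.dimension_scores, batch, alpha=config.alpha
    )
    assoc.results.to_csv(out / "sev_dim_association.tsv", sep="\t", index=False)

    confounders = state["dims_vs_group"]
    dims = confounders.loc[confounders["significant"], "dimension"].tolist()
    covariates = model.dimension_scores[dims] if dims else None
    group = state["pheno"]["case_control"]
    ewas, lam = association.ewas_lite(
        state["beta_qc"], group, covariates, batch, config.genomewide_threshold
    )
    ewas.sort_values("p").head(50).to_csv(out / "ewas_top50.tsv", sep="\t")
    expected = np.arange(1, len(ewas) + 1) / (len(ewas) + 1)
    observed = np.clip(np.sort(ewas["p"].to_numpy()), 1e-300, 1.0)
    qq = pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(observed)}
    )
    qq.to_csv(out / "qq_data.tsv", sep="\t", index=False)
    return {
        "significant_dimensions": assoc.results.loc[
            assoc.results["significant"], "dimension"
        ].tolist(),
        "genomewide_hits": int(ewas["genomewide"].sum()),
        "lambda": lam,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "call": _stage_call,
    "enrich": _stage_enrich,
    "famd": _stage_famd,
    "associate": _stage_associate,
}
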