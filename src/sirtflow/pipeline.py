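"""Configuration-driven orchestration of all five analysis stages.

Stages communicate only through files in the run's output directory, each
stage writes its own tables, and the run ends with a machine-readable
``summary.json`` plus a human-readable ``report.md``, both stamped with the
seed and a hash of the configuration.  For a fixed config and seed the
whole run is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from sirtflow import diffexpr, enrichment, frap, imaging, io, kinetics, simulate

__all__ = ["RunConfig", "run_all", "STAGES"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Which stages to run, their parameter blocks, the master seed and output dir."""

    stages: list[str]
    outdir: Path
    seed: int = 0
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        cfg = json.loads(Path(path).read_text())
        return cls(
            stages=cfg.get("stages", list(STAGES)),
            outdir=Path(cfg.get("outdir", "sirtflow_run")),
            seed=int(cfg.get("seed", 0)),
            params=cfg.get("params", {}),
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            {"stages": self.stages, "seed": self.seed, "params": self.params},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Independent, reproducible sub-seed per stage (below 2**31)."""
    idx = list(STAGES).index(stage)
    return int(np.random.SeedSequence([master_seed, idx]).generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------
# Stage runners: each takes (params, seed, stage_dir) and returns a summary
# --------------------------------------------------------------------------

def _run_kinetics(params: dict, seed: int, outdir: Path) -> dict:
    import dataclasses

    truth = dataclasses.replace(simulate.REFERENCE_KINETICS, seed=seed,
                                **params.get("truth", {}))
    rel_noise = params.get("rel_noise", 0.02)
    rates_pep = simulate.gen_initial_rates(truth, "pep", params.get("pep_top", 160.0),
                                           rel_noise=rel_noise)
    truth_nad = dataclasses.replace(truth, seed=seed + 1)
    rates_nad = simulate.gen_initial_rates(truth_nad, "nad", params.get("nad_top", 1000.0),
                                           rel_noise=rel_noise, fixed_pep=10.0)
    fit_pep = kinetics.fit_michaelis_menten(rates_pep)
    fit_nad = kinetics.fit_michaelis_menten(rates_nad)
    summary = kinetics.summarize_kinetics(fit_pep, fit_nad, truth.enzyme_conc)
    pd.DataFrame(rates_pep, columns=["s_um", "v_um_per_min"]).to_csv(
        outdir / "rates_peptide.tsv", sep="\t", index=False)
    pd.DataFrame(rates_nad, columns=["s_um", "v_um_per_min"]).to_csv(
        outdir / "rates_nad.tsv", sep="\t", index=False)
    out = {
        "km_pep_um": fit_pep.km, "km_pep_se": fit_pep.km_se,
        "km_nad_um": fit_nad.km, "km_nad_se": fit_nad.km_se,
        "kcat_per_min": summary.kcat_per_min, "kcat_per_s": summary.kcat_per_s,
        "specificity_per_M_per_s": summary.specificity,
        "converged": summary.converged,
        "truth": {"kcat": truth.kcat, "km_pep": truth.km_pep, "km_nad": truth.km_nad},
    }
    io.write_json(out, outdir / "kinetics_summary.json")
    return out


def _run_imaging(params: dict, seed: int, outdir: Path) -> dict:
    conditions = params.get("conditions", {"resting": 0.9, "stimulated": 2.0})
    n_cells = params.get("n_cells", 100)
    noise_sd = params.get("noise_sd", 5.0)
    summaries = {}
    ratios = {}
    for i, (label, true_ratio) in enumerate(conditions.items()):
        truth = simulate.CellFieldTruth(n_cells=n_cells, true_ratio=true_ratio,
                                        noise_sd=noise_sd, seed=seed + i)
        fld = simulate.gen_cell_field(truth)
        labels = imaging.segment_nuclei(fld.nuclear_channel)
        cells = imaging.measure_cells(fld.stain_channel, labels,
                                      ring_width_px=truth.ring_width_px)
        pd.DataFrame(cells).to_csv(outdir / f"cells_{label}.csv", index=False)
        summ = imaging.summarize_condition(cells, label)
        summaries[label] = summ
        ratios[label] = [c.ratio for c in cells]
    pd.DataFrame([s.__dict__ for s in summaries.values()]).to_csv(
        outdir / "condition_summaries.tsv", sep="\t", index=False)
    out = {label: {"n_cells": s.n_cells, "mean_ratio": s.mean_ratio,
                   "sem_ratio": s.sem_ratio, "n_positive": s.n_positive}
           for label, s in summaries.items()}
    labels = list(conditions)
    if len(labels) == 2:
        stat, p = imaging.compare_conditions(ratios[labels[0]], ratios[labels[1]])
        out["comparison"] = {"groups": labels, "statistic": stat, "p": p}
    io.write_json(out, outdir / "imaging_summary.json")
    return out


def _run_frap(params: dict, seed: int, outdir: Path) -> dict:
    groups = params.get("groups", {"control": 2.0, "overexpressing": 2.0})
    n_traces = params.get("n_traces", 24)
    noise_sd = params.get("noise_sd", 0.01)
    halftimes: dict[str, list[float]] = {}
    fits_out = {}
    for gi, (label, tau) in enumerate(groups.items()):
        fits = []
        for j in range(n_traces):
            truth = simulate.FrapTruth(tau_s=tau, noise_sd=noise_sd,
                                       seed=seed + 1000 * gi + j)
            trace = frap.normalize_trace(simulate.gen_frap_trace(truth))
            fits.append(frap.fit_recovery(trace))
        halftimes[label] = [f.t_half_s for f in fits]
        fits_out[label] = [f.__dict__ for f in fits]
    io.write_json(fits_out, outdir / "frap_fits.json")
    comparisons = frap.compare_halftimes(halftimes)
    out = {
        "mean_t_half_s": {k: float(np.mean(v)) for k, v in halftimes.items()},
        "comparisons": comparisons,
    }
    io.write_json(out, outdir / "frap_summary.json")
    return out


def _run_diffexpr(params: dict, seed: int, outdir: Path) -> dict:
    truth = simulate.tnfa_truth(
        n_probes=params.get("n_probes", 2000),
        n_up=params.get("n_up", 153),
        n_down=params.get("n_down", 45),
        replicate_sd=params.get("replicate_sd", 0.25),
        seed=seed,
    )
    matrix = simulate.gen_expression_experiment(truth)
    io.write_expression(matrix, outdir / "expression.tsv")
    results = {}
    tables = {}
    for test, ref in (("h", "g"), ("b", "a")):
        table = diffexpr.fit_contrast(matrix, diffexpr.Contrast(test=test, ref=ref))
        tables[(test, ref)] = table
        table.to_csv(outdir / f"contrast_{test}_vs_{ref}.tsv", sep="\t",
                     index_label="probe_id")
        n_up, n_down = diffexpr.de_counts(table)
        results[f"{test}_vs_{ref}"] = {"n_up": n_up, "n_down": n_down}
    overlap = diffexpr.overlap_profiles(tables[("h", "g")], tables[("b", "a")])
    planted_up = {simulate.probe_id(i) for i in truth.planted_up("h", "g")}
    planted_down = {simulate.probe_id(i) for i in truth.planted_down("h", "g")}
    results["overlap"] = {"n_up": overlap.n_up, "n_down": overlap.n_down}
    results["planted"] = {"n_up": len(planted_up), "n_down": len(planted_down)}
    profile = overlap.up | overlap.down
    if profile:
        results["similarity_to_planted"] = diffexpr.profile_similarity(
            profile, planted_up | planted_down)
    io.write_gene_list(profile, outdir / "response_profile.txt")
    io.write_json(results, outdir / "diffexpr_summary.json")
    return results


def _run_enrichment(params: dict, seed: int, outdir: Path) -> dict:
    truth = simulate.reference_regulon_truth(seed=seed)
    db, query = simulate.gen_regulon_db(truth)
    io.write_gmt({k: v for k, v in db.regulons.items()}, outdir / "regulons.gmt")
    io.write_gene_list(query, outdir / "query.txt")
    rows = enrichment.tf_connectivity(query, db)
    table = enrichment.connectivity_table(rows)
    table.to_csv(outdir / "tf_connectivity.tsv", sep="\t", index=False)

    # PAGE demo: one genuinely shifted pathway among nulls on a synthetic
    # genome-wide fold-change vector
    rng = np.random.default_rng(seed + 7)
    n_genes = params.get("page_background_n", 5000)
    genes = [simulate.gene_id(i) for i in range(n_genes)]
    fc = rng.normal(0.0, 1.0, n_genes)
    shifted = rng.choice(n_genes, size=40, replace=False)
    fc[shifted] += params.get("page_shift", 1.0)
    pathways = {"shifted_pathway": [genes[i] for i in shifted]}
    for j in range(params.get("page_null_sets", 9)):
        members = rng.choice(n_genes, size=40, replace=False)
        pathways[f"null_pathway_{j}"] = [genes[i] for i in members]
    page = enrichment.page_table(pd.Series(fc, index=genes), pathways)
    page.to_csv(outdir / "page_scores.tsv", sep="\t", index=False)
    out = {
        "top_tf": table.iloc[0]["tf"],
        "tf_rows": table.to_dict(orient="records"),
        "top_pathway": page.iloc[0]["pathway"] if len(page) else None,
    }
    io.write_json(out, outdir / "enrichment_summary.json")
    return out


STAGES: dict[str, Callable[[dict, int, Path], dict]] = {
    "kinetics": _run_kinetics,
    "imaging": _run_imaging,
    "frap": _run_frap,
    "diffexpr": _run_diffexpr,
    "enrichment": _run_enrichment,
}


def run_all(config: RunConfig) -> dict:
    """Execute the requested stages and write summary.json plus report.md.

    Any stage failure aborts the run with a stage-tagged error; outputs of
    already-completed stages are retained in the output directory.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    for stage in config.stages:
        stage_dir = config.outdir / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        sseed = stage_seed(config.seed, stage)
        logger.info("stage %s (seed %d)", stage, sseed)
        try:
            summary["stages"][stage] = STAGES[stage](
                config.params.get(stage, {}), sseed, stage_dir
            )
        except Exception as exc:  # noqa: BLE001 - re-tagged and re-raised
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    io.write_json(summary, config.outdir / "summary.json")
    _write_report(summary, config.outdir / "report.md")
    return summary


def _write_report(summary: dict, path: Path) -> None:
    lines = [
        "# sirtflow run report",
        "",
        f"seed: {summary['seed']}  ",
        f"config hash: {summary['config_hash']}",
        "",
    ]
    for stage, result in summary["stages"].items():
        lines.append(f"## {stage}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(io._jsonable(result), indent=2, sort_keys=True))
        lines.append("```")
        lines.append("")
    Path(path).write_text("\n".join(lines))
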