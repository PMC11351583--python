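"""End-to-end pipeline: simulate (or load) -> DE -> interactome -> enrichment.

A run is driven by one structured YAML/dict config and writes every stage's
table plus a machine-readable ``summary.json`` under the output directory.
Fixed seed implies byte-identical outputs.  ``summarize_run`` recomputes all
counts from the written tables and verifies them against the stored summary.
"""

from __future__ import annotations

import json
import logging
import sys
import time

from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import DEConfig, nb_wald_test, size_factors
from .io import (
    FormatError,
    read_count_matrix,
    read_gmt,
    read_pair_table,
    read_sample_table,
    write_count_matrix,
    write_pair_table,
    write_sample_table,
)
from .interactome import (
    InteractomeConfig,
    consensus_pairs,
    export_network,
    pearson_pair_correlations,
    select_final_pairs,
)
from .ora import enrich_collection
from .simulate import (
    SimulationConfig,
    config_to_dict,
    simulate_gene_sets,
    simulate_paired_experiment,
    simulate_prediction_db,
    simulate_validation_db,
)

logger = logging.getLogger("mirlink")

__all__ = ["run_pipeline", "summarize_run", "load_config", "default_config", "IntegrityError"]


class IntegrityError(RuntimeError):
    """A run directory's tables disagree with its stored summary."""


def default_config() -> dict:
    """Reference config with every default documented by construction."""
    return {
        "mode": "synthetic",  # or "files"
        "simulation": config_to_dict(SimulationConfig()),
        "inputs": {  # used in files mode
            "mrna_counts": None,
            "mirna_counts": None,
            "samples": None,
            "predictions": None,
            "validations": None,
            "gene_sets": None,  # optional GMT
        },
        "de": {"tau_fdr": 0.05, "tau_fc": 0.5, "min_total_count": 10,
               "dispersion_floor": 1e-8, "pseudocount": 1.0, "use_raw_p": False},
        "interactome": {"min_tools": 3, "min_sharing": 2, "r_max": -0.7, "p_max": 0.05,
                        "require_validated": True, "require_anticorrelation_sign": True,
                        "correlation_input": "log2_normalized"},
        "enrichment": {"alpha": 0.05, "use_q": False, "n_synthetic_sets": 50},
    }


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as handle:
        user = yaml.safe_load(handle) or {}
    cfg = default_config()
    for section, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(value)
        else:
            cfg[section] = value
    return cfg


def _setup_run_logging(outdir: Path, verbose: bool) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        stream = logging.StreamHandler(sys.stderr)
        stream.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(stream)
    return handler


def _load_inputs(cfg: dict, outdir: Path):
    """Materialise the six input tables, simulating them in synthetic mode."""
    if cfg["mode"] == "synthetic":
        sim_cfg = SimulationConfig(**{
            **cfg["simulation"],
            "baseline_mean_log_range": tuple(cfg["simulation"]["baseline_mean_log_range"]),
            "tool_names": tuple(cfg["simulation"]["tool_names"]),
            "validation_sources": tuple(cfg["simulation"]["validation_sources"]),
        })
        mrna, mirna, samples, truth = simulate_paired_experiment(sim_cfg)
        predictions = simulate_prediction_db(truth, sim_cfg)
        validations = simulate_validation_db(truth, sim_cfg)
        collections = {"synthetic": simulate_gene_sets(
            sim_cfg, n_sets=cfg["enrichment"]["n_synthetic_sets"])}
        write_count_matrix(mrna, outdir / "counts_mrna.tsv")
        write_count_matrix(mirna, outdir / "counts_mirna.tsv")
        write_sample_table(samples, outdir / "samples.tsv")
        write_pair_table(predictions, outdir / "predictions.tsv")
        write_pair_table(validations, outdir / "validations.tsv")
        truth.to_json(outdir / "truth.json")
        return mrna, mirna, samples, predictions, validations, collections, truth
    paths = cfg["inputs"]
    required = ["mrna_counts", "mirna_counts", "samples", "predictions", "validations"]
    missing = [k for k in required if not paths.get(k)]
    if missing:
        raise FormatError(f"files mode requires input paths for {missing}")
    for k in required + (["gene_sets"] if paths.get("gene_sets") else []):
        if not Path(paths[k]).exists():
            raise FormatError(f"input file for {k!r} not found: {paths[k]}")
    mrna = read_count_matrix(paths["mrna_counts"])
    mirna = read_count_matrix(paths["mirna_counts"])
    samples = read_sample_table(paths["samples"])
    predictions = read_pair_table(paths["predictions"], kind="prediction")
    validations = read_pair_table(paths["validations"], kind="validation")
    collections = {}
    if paths.get("gene_sets"):
        collections["user"] = read_gmt(paths["gene_sets"])
    return mrna, mirna, samples, predictions, validations, collections, None


def run_pipeline(
    config: dict | str | Path, outdir: str | Path, seed: int | None = None,
    verbose: bool = False,
) -> dict:
    """Execute every stage and return the run summary (also written as JSON)."""
    if isinstance(config, dict):
        user = json.loads(json.dumps(config))  # deep copy, reject non-JSON values early
        cfg = default_config()
        for section, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(section), dict):
                cfg[section].update(value)
            else:
                cfg[section] = value
    else:
        cfg = load_config(config)
    if seed is not None:
        cfg.setdefault("simulation", {})["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(outdir, verbose)
    t0 = time.time()
    stage = "inputs"
    try:
        logger.info("stage inputs: mode=%s", cfg["mode"])
        mrna, mirna, samples, predictions, validations, collections, truth = _load_inputs(cfg, outdir)
        samples.check_paired(mrna)
        samples.check_paired(mirna)

        stage = "diff_expr"
        de_cfg = DEConfig(**cfg["de"])
        logger.info("stage diff_expr: %d genes, %d miRNAs, %d vs %d samples",
                    mrna.shape[0], mirna.shape[0], len(samples.case_ids), len(samples.control_ids))
        de_mrna = nb_wald_test(mrna, samples, de_cfg)
        de_mirna = nb_wald_test(mirna, samples, de_cfg)
        de_mrna.to_csv(outdir / "de_mrna.tsv", sep="\t", index=False, lineterminator="\n")
        de_mirna.to_csv(outdir / "de_mirna.tsv", sep="\t", index=False, lineterminator="\n")
        degs = list(de_mrna.loc[de_mrna["called"], "feature"])
        dems = list(de_mirna.loc[de_mirna["called"], "feature"])

        stage = "interactome"
        int_cfg = InteractomeConfig(**cfg["interactome"])
        pairs = consensus_pairs(dems, degs, predictions, k=int_cfg.min_tools)
        s_mirna = size_factors(mirna)
        s_mrna = size_factors(mrna)
        correlations = pearson_pair_correlations(pairs, mirna, mrna, s_mirna, s_mrna, int_cfg)
        correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False, lineterminator="\n")
        edges, stage_counts = select_final_pairs(
            pairs, correlations, de_mirna, de_mrna, int_cfg, validated=validations
        )
        export_network(edges, outdir / "edges.tsv", format="edge_tsv")
        export_network(edges, outdir / "network.graphml", format="graphml")
        logger.info("stage interactome: %s", stage_counts)

        stage = "enrichment"
        enrichments = enrich_collection(
            de_mrna, collections, alpha=cfg["enrichment"]["alpha"], use_q=cfg["enrichment"]["use_q"]
        )
        enrich_counts = {}
        for name, frame in enrichments.items():
            frame.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False, lineterminator="\n")
            enrich_counts[name] = int(frame["significant"].sum()) if len(frame) else 0

        summary = {
            "tool": "mirlink",
            "version": __version__,
            "seed": cfg.get("simulation", {}).get("seed"),
            "config": cfg,
            "stages": {
                "inputs": {
                    "mode": cfg["mode"],
                    "n_genes": mrna.shape[0],
                    "n_mirnas": mirna.shape[0],
                    "n_case": len(samples.case_ids),
                    "n_control": len(samples.control_ids),
                    "n_prediction_records": int(len(predictions)),
                    "n_validation_records": int(len(validations)),
                },
                "diff_expr": {
                    "genes_tested": int(len(de_mrna)),
                    "mirnas_tested": int(len(de_mirna)),
                    "deg_total": len(degs),
                    "deg_up": int((de_mrna["called"] & (de_mrna["log2fc"] > 0)).sum()),
                    "deg_down": int((de_mrna["called"] & (de_mrna["log2fc"] < 0)).sum()),
                    "dem_total": len(dems),
                    "dem_up": int((de_mirna["called"] & (de_mirna["log2fc"] > 0)).sum()),
                    "dem_down": int((de_mirna["called"] & (de_mirna["log2fc"] < 0)).sum()),
                },
                "interactome": {**{k: int(v) for k, v in stage_counts.items()},
                                "final_edges": int(len(edges))},
                "enrichment": {"significant_sets": enrich_counts},
            },
            "runtime_seconds": round(time.time() - t0, 3),
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        logger.info("run complete in %.1fs", time.time() - t0)
        return summary
    except Exception:
        logger.exception("stage %s failed", stage)
        (outdir / "summary.json").write_text(
            json.dumps({"failed_stage": stage, "tool": "mirlink", "version": __version__}) + "\n"
        )
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def summarize_run(outdir: str | Path) -> dict:
    """Recompute stage counts from the written tables and verify the summary."""
    outdir = Path(outdir)
    required = ["summary.json", "de_mrna.tsv", "de_mirna.tsv", "edges.tsv"]
    missing = [f for f in required if not (outdir / f).exists()]
    if missing:
        raise IntegrityError(f"run directory is missing artifact(s): {missing}")
    summary = json.loads((outdir / "summary.json").read_text())
    if "stages" not in summary:
        raise IntegrityError(f"summary records a failed run: {summary}")

    de_mrna = pd.read_csv(outdir / "de_mrna.tsv", sep="\t")
    de_mirna = pd.read_csv(outdir / "de_mirna.tsv", sep="\t")
    edges = pd.read_csv(outdir / "edges.tsv", sep="\t") if (outdir / "edges.tsv").stat().st_size else pd.DataFrame()
    checks = {
        "diff_expr": {
            "genes_tested": len(de_mrna),
            "deg_total": int(de_mrna["called"].sum()) if len(de_mrna) else 0,
            "mirnas_tested": len(de_mirna),
            "dem_total": int(de_mirna["called"].sum()) if len(de_mirna) else 0,
        },
        "interactome": {"final_edges": int(len(edges))},
    }
    for stage_name, expected in checks.items():
        recorded = summary["stages"][stage_name]
        for key, value in expected.items():
            if int(recorded[key]) != int(value):
                raise IntegrityError(
                    f"stage {stage_name!r}: recomputed {key}={value} but summary records {recorded[key]}"
                )
    cascade = summary["stages"]["interactome"]
    order = ["consensus", "validated", "shared", "correlation", "final"]
    values = [cascade[k] for k in order if k in cascade]
    if any(a < b for a, b in zip(values, values[1:])):
        raise IntegrityError(f"filter-cascade counts are not non-increasing: {cascade}")
    return summary
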