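"""End-to-end orchestration: simulate/read -> impute -> screen -> score -> network.

Stages communicate through on-disk tab-delimited tables so each is
independently re-runnable; a JSON manifest records the configuration, the
seed, stage timings, output digests and library versions. Given the same
seed, every output table is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dep_screening import screen_deps, summarize_calls
from .immune_scoring import compare_groups, immune_score, score_collection
from .io_formats import (
    AbundanceMatrix,
    GeneSetCollection,
    PipelineConfig,
    center_samples,
    read_abundance_matrix,
    read_gmt,
    write_table,
)
from .missingness import sectionalized_impute
from .network_hub import build_tom_network, hub_consensus, pca_contributions
from .synthetic_data import SyntheticSpec, simulate, toy_gene_sets

__all__ = ["validate_config", "run_pipeline"]

log = logging.getLogger(__name__)

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def validate_config(raw: dict | None) -> PipelineConfig:
    """Build a PipelineConfig from a raw mapping, rejecting unknown keys."""
    raw = dict(raw or {})
    unknown = [k for k in raw if k not in _CONFIG_FIELDS]
    if unknown:
        key = unknown[0]
        hint = difflib.get_close_matches(key, _CONFIG_FIELDS, n=1, cutoff=0.5)
        suffix = f"; did you mean {hint[0]!r}?" if hint else ""
        raise ValueError(f"unknown config key {key!r}{suffix}")
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig | dict | None,
    outdir,
    *,
    matrix_path=None,
    annotation_path=None,
    synthetic_spec: SyntheticSpec | None = None,
    gmt_path=None,
    linear_scale: bool = False,
    seed: int | None = None,
) -> Path:
    """Run every stage and write the result tables plus a manifest.

    Input is either a matrix/annotation file pair or a synthetic
    specification. Writes six tables: missingness_report, completed_matrix,
    dep_table, immune_scores, immune_comparison, network_hubs.
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    if seed is None:
        seed = config.rng_seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {
        "config": config.to_dict(),
        "seed": int(seed),
        "versions": {
            "proteosect": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "conventions": {
            "scale": "log2, per-sample median-centered",
            "knn": "protein neighbours, overlap-normalised Euclidean, "
                   "inverse-distance weights",
            "imputation_order": "downshift first, then KNN on observed+downshifted",
            "levene": "median-centered (Brown-Forsythe)",
            "ssgsea_score": "integrated running sum",
            "centrality": "intramodular TOM connectivity",
        },
        "results": {},
    }

    # ---- input stage ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if synthetic_spec is not None:
            spec = dataclasses.replace(synthetic_spec, seed=int(seed))
            matrix, _truth = simulate(spec)
            manifest["input"] = {"synthetic_spec": dataclasses.asdict(spec)}
        else:
            if matrix_path is None or annotation_path is None:
                raise ValueError("matrix_path and annotation_path are required")
            matrix = read_abundance_matrix(
                matrix_path,
                annotation_path,
                linear_scale=linear_scale,
                zeros_are_missing=config.zeros_are_missing,
            )
            matrix, _ = center_samples(matrix)
            manifest["input"] = {
                "matrix": str(matrix_path),
                "annotation": str(annotation_path),
            }
    except Exception as exc:
        raise RuntimeError(f"io stage failed: {exc}") from exc
    timings["io"] = time.perf_counter() - t0

    # ---- imputation -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        result = sectionalized_impute(matrix, config, seed=seed)
    except Exception as exc:
        raise RuntimeError(f"imputation stage failed: {exc}") from exc
    write_table(result.report.table, outdir / "missingness_report.tsv")
    completed_df = result.matrix.to_dataframe()
    completed_df.index.name = "protein_id"
    write_table(completed_df, outdir / "completed_matrix.tsv")
    manifest["results"]["threshold1"] = result.threshold1
    manifest["results"]["n_proteins_retained"] = result.matrix.n_proteins
    manifest["results"]["missing_totals"] = result.report.totals
    timings["impute"] = time.perf_counter() - t0

    # ---- differential screening ------------------------------------------
    t0 = time.perf_counter()
    try:
        dep_table = screen_deps(result.matrix, config)
    except Exception as exc:
        raise RuntimeError(f"dep stage failed: {exc}") from exc
    write_table(dep_table, outdir / "dep_table.tsv")
    manifest["results"]["dep_calls"] = summarize_calls(dep_table)
    timings["dep"] = time.perf_counter() - t0

    # ---- immune scoring ---------------------------------------------------
    t0 = time.perf_counter()
    try:
        if gmt_path is not None:
            sets = read_gmt(gmt_path)
        else:
            sets = toy_gene_sets(result.matrix.protein_ids, seed=int(seed))
        score_matrix = score_collection(result.matrix, sets, config.ssgsea_alpha)
        scores = immune_score(score_matrix, score_matrix.set_names)
        p, means, direction = compare_groups(scores, result.matrix.group_of)
    except Exception as exc:
        raise RuntimeError(f"immune stage failed: {exc}") from exc
    write_table(score_matrix.scores, outdir / "immune_scores.tsv")
    comparison = pd.DataFrame(
        [
            {
                "statistic": "immune_score",
                "p_value": p,
                "higher_group": direction,
                **{f"mean_{g}": v for g, v in sorted(means.items())},
            }
        ]
    ).set_index("statistic")
    write_table(comparison, outdir / "immune_comparison.tsv")
    timings["immune"] = time.perf_counter() - t0

    # ---- network / hub ----------------------------------------------------
    t0 = time.perf_counter()
    dep_ids = list(dep_table.index[dep_table["call"] != "ns"])
    try:
        if len(dep_ids) >= 3:
            dep_values = result.matrix.subset_proteins(dep_ids).to_dataframe()
            network = build_tom_network(
                dep_values, config.soft_power, config.n_modules
            )
            contrib = pca_contributions(dep_values, min(5, min(dep_values.shape)))
            hubs = hub_consensus(
                network.centrality, contrib.aggregate, top_k=len(dep_ids)
            )
            hubs = hubs.join(network.module_of)
            hubs["is_hub"] = hubs["centrality"] > config.centrality_cut
            manifest["results"]["n_network_nodes"] = len(dep_ids)
            manifest["results"]["centrality_definition"] = (
                "intramodular TOM connectivity; cut at "
                f"{config.centrality_cut} (configurable)"
            )
        else:
            hubs = pd.DataFrame(
                columns=[
                    "centrality", "contribution", "rank_centrality",
                    "rank_contribution", "rank_sum", "consensus_rank",
                    "module", "is_hub",
                ]
            )
            hubs.index.name = "node_id"
            manifest["results"]["n_network_nodes"] = len(dep_ids)
            log.warning("fewer than 3 differential proteins; network stage empty")
    except Exception as exc:
        raise RuntimeError(f"network stage failed: {exc}") from exc
    write_table(hubs, outdir / "network_hubs.tsv")
    timings["network"] = time.perf_counter() - t0

    manifest["timings_s"] = {k: round(v, 4) for k, v in timings.items()}
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
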