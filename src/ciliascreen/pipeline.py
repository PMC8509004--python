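"""End-to-end orchestration: simulate/load -> screen -> downstream tables.

``run_pipeline`` drives the stages from a plain configuration mapping
(typically parsed from YAML), writes every stage table under one output
directory, and records a manifest with the seed, package versions and input
checksums.  Identical configuration and seed give byte-identical outputs.

All downstream tables (region summary, overlap matrix, shared-in-k,
compartment summaries) are derived from ``screen_results.tsv`` alone, which
is therefore the single source of truth of a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .age_screen import (
    ScreenConfig,
    annotate_degas,
    call_degas,
    region_summary,
    screen_all,
    volcano_table,
)
from .coexpression import cluster_order, pearson_matrix, reorder, write_correlation
from .compartments import compartment_summary, compartment_summary_by_region
from .data_io import (
    ExpressionMatrix,
    load_gene_list,
    packaged_gene_panel_path,
    read_brainspan_triplet,
    write_brainspan_triplet,
)
from .region_sets import (
    build_network,
    export_network,
    overlap_matrix,
    shared_in_k,
    write_overlap,
    write_shared_in_k,
)
from .synthetic_data import (
    SimConfig,
    default_annotations,
    generate_dataset,
    write_ground_truth,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "screen", "coexpr", "overlap", "compartments")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _screen_config(cfg: dict) -> ScreenConfig:
    section = cfg.get("screen", {}) or {}
    return ScreenConfig(
        alpha_raw=float(section.get("alpha_raw", 0.05)),
        fdr_alpha=float(section.get("fdr_alpha", 0.05)),
        min_samples=int(section.get("min_samples", 3)),
        per_region_fdr=bool(section.get("per_region_fdr", False)),
    )


def _sim_config(cfg: dict) -> SimConfig:
    section = dict(cfg.get("simulate", {}) or {})
    if "regions" in section:
        section["regions"] = tuple(section["regions"])
    for pair_key in ("slope_range", "intercept_range"):
        if pair_key in section:
            section[pair_key] = tuple(section[pair_key])
    section.setdefault("seed", int(cfg.get("seed", 0)))
    return SimConfig(**section)


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    Configuration keys: ``seed``, ``out_dir``, ``stages`` (subset of
    simulate/screen/coexpr/overlap/compartments; default all), ``simulate``
    (SimConfig fields), ``screen`` (ScreenConfig fields),
    ``expression_dir`` and ``gene_list`` (used when not simulating; the
    gene list defaults to the packaged synthetic panel).
    """
    out_dir = Path(out_dir or config.get("out_dir", "ciliascreen_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    seed = int(config.get("seed", 0))

    manifest: dict = {
        "package": "ciliascreen",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "stages": stages,
        "inputs": {},
        "outputs": [],
    }
    outputs: list[Path] = []
    t_start = time.perf_counter()

    try:
        matrix, samples, annotations = _acquire_inputs(
            config, out_dir, seed, stages, manifest, outputs
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-named abort
        raise PipelineError(f"stage simulate/io failed: {exc}") from exc

    screen_cfg = _screen_config(config)
    results = None
    dega_sets = None
    symbols = [a.symbol for a in annotations]

    if "screen" in stages:
        stage_t = time.perf_counter()
        try:
            results = screen_all(
                matrix, samples, gene_list=annotations, config=screen_cfg
            )
            annotated = annotate_degas(results, screen_cfg)
            dega_sets = call_degas(results, screen_cfg)
            path = out_dir / "screen_results.tsv"
            annotated.to_csv(path, sep="\t", index=False)
            outputs.append(path)
            summary = region_summary(dega_sets, len(symbols))
            path = out_dir / "region_summary.tsv"
            summary.to_csv(path, sep="\t", index=False)
            outputs.append(path)
            for region in dega_sets.regions:
                table = volcano_table(results, region)
                path = out_dir / f"volcano_{region}.tsv"
                table.to_csv(path, sep="\t", index=False)
                outputs.append(path)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage screen failed: {exc}") from exc
        log.info("stage screen: %.2fs", time.perf_counter() - stage_t)

    if "coexpr" in stages:
        if dega_sets is None:
            raise PipelineError("stage coexpr requires the screen stage")
        stage_t = time.perf_counter()
        try:
            for region in dega_sets.regions:
                genes = sorted(dega_sets.genes(region))
                if len(genes) < 2:
                    log.warning(
                        "skipping correlation for %s (< 2 DEGAs)", region
                    )
                    continue
                R = pearson_matrix(matrix, samples, genes, region)
                R = reorder(R, cluster_order(R))
                path = write_correlation(R, out_dir / f"corr_{region}.tsv")
                outputs.append(path)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage coexpr failed: {exc}") from exc
        log.info("stage coexpr: %.2fs", time.perf_counter() - stage_t)

    if "overlap" in stages:
        if dega_sets is None:
            raise PipelineError("stage overlap requires the screen stage")
        stage_t = time.perf_counter()
        try:
            counts = overlap_matrix(dega_sets)
            outputs.append(write_overlap(counts, out_dir / "overlap_matrix.tsv"))
            gene_k, _, _ = shared_in_k(dega_sets)
            outputs.append(
                write_shared_in_k(gene_k, out_dir / "shared_in_k.tsv")
            )
            graph = build_network(dega_sets)
            export_network(
                graph,
                out_dir / "network.graphml",
                out_dir / "network_edges.tsv",
            )
            outputs.extend(
                [out_dir / "network.graphml", out_dir / "network_edges.tsv"]
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage overlap failed: {exc}") from exc
        log.info("stage overlap: %.2fs", time.perf_counter() - stage_t)

    if "compartments" in stages:
        if dega_sets is None:
            raise PipelineError("stage compartments requires the screen stage")
        stage_t = time.perf_counter()
        try:
            summary_all = compartment_summary(
                dega_sets, annotations, screened_genes=symbols
            )
            path = out_dir / "compartment_summary_all.tsv"
            summary_all.to_csv(path, sep="\t", index=False)
            outputs.append(path)
            by_region = compartment_summary_by_region(
                dega_sets, annotations, screened_genes=symbols
            )
            path = out_dir / "compartment_summary_by_region.tsv"
            by_region.to_csv(path, sep="\t", index=False)
            outputs.append(path)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage compartments failed: {exc}") from exc
        log.info("stage compartments: %.2fs", time.perf_counter() - stage_t)

    manifest["outputs"] = sorted(p.name for p in outputs)
    manifest["runtime_seconds"] = round(time.perf_counter() - t_start, 3)
    manifest_path = out_dir / "manifest.json"
    manifest_for_disk = dict(manifest)
    manifest_for_disk.pop("runtime_seconds")  # keep reruns byte-identical
    manifest_path.write_text(
        json.dumps(manifest_for_disk, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _acquire_inputs(config, out_dir, seed, stages, manifest, outputs):
    """Simulate a dataset or load the triplet named in the config."""
    if "simulate" in stages:
        sim_cfg = _sim_config(config)
        matrix, samples, ground_truth = generate_dataset(sim_cfg)
        triplet_dir = out_dir / "triplet"
        paths = write_brainspan_triplet(matrix, samples, triplet_dir)
        outputs.extend(paths.values())
        outputs.append(
            write_ground_truth(ground_truth, out_dir / "ground_truth.tsv")
        )
        annotations = default_annotations(matrix.gene_symbols)
        from .data_io import write_gene_list

        outputs.append(write_gene_list(annotations, out_dir / "gene_list.tsv"))
        manifest["simulate"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(sim_cfg).items()
        }
        return matrix, samples, annotations

    expr_dir = config.get("expression_dir")
    if expr_dir is None:
        raise PipelineError(
            "stage io failed: provide expression_dir or enable simulate"
        )
    expr_dir = Path(expr_dir)
    triplet = {
        "expression": expr_dir / "expression_matrix.csv",
        "columns": expr_dir / "columns_metadata.csv",
        "rows": expr_dir / "rows_metadata.csv",
    }
    matrix, samples = read_brainspan_triplet(
        triplet["expression"], triplet["columns"], triplet["rows"]
    )
    gene_list_path = Path(config.get("gene_list") or packaged_gene_panel_path())
    annotations = load_gene_list(gene_list_path)
    for role, path in {**triplet, "gene_list": gene_list_path}.items():
        manifest["inputs"][role] = {
            "path": str(path), "sha256": _sha256(Path(path)),
        }
    return matrix, samples, annotations
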