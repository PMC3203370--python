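"""End-to-end orchestration: load -> preprocess -> ica -> nsnmf -> select -> integrate.

Stages communicate only through files under the output directory, so each
stage is independently inspectable and a rerun with the same config and
inputs reproduces every artifact bitwise. The manifest JSON records the
config, the seed lineage, per-file checksums and the component selections.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import select as sel
from .datatypes import ExpressionMatrix, GeneFactorError, PhenotypeLabels
from .ica import ICAResult, fastica_consensus
from .io import (
    RunConfig,
    get_logger,
    read_expression_matrix,
    read_phenotypes,
    write_expression_matrix,
    write_table,
)
from .nsnmf import NsNMFResult, nsnmf_multistart
from .preprocess import make_nonnegative, standardize_samples

__all__ = ["run_all", "StageError"]

STAGES = ("load", "preprocess", "ica", "nsnmf", "select", "integrate")


class StageError(GeneFactorError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _matrix_table(values: np.ndarray, row_ids, col_ids, index_name: str) -> pd.DataFrame:
    df = pd.DataFrame(values, index=list(row_ids), columns=list(col_ids))
    df.index.name = index_name
    return df


def run_all(
    config: RunConfig,
    expression_path: str | Path,
    phenotype_path: str | Path,
    out_dir: str | Path,
) -> dict:
    """Run the full two-track analysis; returns the manifest dict.

    Any stage error aborts with :class:`StageError` naming the stage;
    artifacts written by earlier stages stay on disk.
    """
    log = get_logger()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": [],
        "files": {},
        "selected_ica_components": None,
    }
    written: list[Path] = []

    def emit_df(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        written.append(path)

    stage = "load"
    try:
        log.info("stage=%s reading %s", stage, expression_path)
        matrix = read_expression_matrix(expression_path)
        labels = read_phenotypes(phenotype_path, matrix)
        manifest["stages"].append(stage)

        stage = "preprocess"
        standardized = standardize_samples(matrix)
        nonneg = make_nonnegative(matrix)
        write_expression_matrix(standardized, out / "standardized.tsv")
        write_expression_matrix(nonneg, out / "nonnegative.tsv")
        written += [out / "standardized.tsv", out / "nonnegative.tsv"]
        manifest["stages"].append(stage)

        stage = "ica"
        log.info("stage=%s %d restarts", stage, config.ica_n_restarts)
        ica_result = fastica_consensus(standardized, config)
        comp_ids = [f"IC{j + 1}" for j in range(ica_result.n_components)]
        emit_df(_matrix_table(ica_result.mixing, matrix.sample_ids, comp_ids,
                              "sample_id"), "ica_mixing.tsv", index=True)
        emit_df(_matrix_table(ica_result.sources, comp_ids, matrix.gene_ids,
                              "component"), "ica_sources.tsv", index=True)
        emit_df(pd.DataFrame({"component": comp_ids,
                              "stability": ica_result.stability,
                              "negentropy": ica_result.objective}),
                "ica_stability.tsv")
        manifest["stages"].append(stage)
        manifest["ica_converged_restarts"] = ica_result.converged_count

        stage = "nsnmf"
        log.info("stage=%s k=%d theta=%.2f %d restarts", stage, config.k,
                 config.theta, config.nsnmf_n_restarts)
        nmf_result = nsnmf_multistart(nonneg, config)
        factor_ids = [f"F{j + 1}" for j in range(nmf_result.k)]
        emit_df(_matrix_table(nmf_result.metagenes, matrix.gene_ids, factor_ids,
                              "gene_id"), "nmf_W.tsv", index=True)
        emit_df(_matrix_table(nmf_result.encodings, factor_ids,
                              matrix.sample_ids, "factor"), "nmf_H.tsv",
                index=True)
        emit_df(pd.DataFrame({"iteration": np.arange(1, nmf_result.objective_trace.size + 1),
                              "kl_objective": nmf_result.objective_trace}),
                "nmf_objective_trace.tsv")
        diag = {
            "best_restart": nmf_result.restart_id,
            "theta": nmf_result.theta,
            "final_objectives": [float(x) for x in nmf_result.restart_objectives],
            "sparseness": [float(x) for x in nmf_result.sparseness],
        }
        (out / "nmf_diagnostics.json").write_text(
            json.dumps(diag, indent=2, sort_keys=True) + "\n")
        written.append(out / "nmf_diagnostics.json")
        manifest["stages"].append(stage)

        stage = "select"
        scores = sel.score_components(ica_result.mixing, labels,
                                      matrix.sample_ids)
        chosen = sel.select_discriminating_components(scores)
        manifest["selected_ica_components"] = chosen
        emit_df(pd.DataFrame([dataclasses.asdict(s) for s in scores]),
                "component_scores.tsv")
        ica_genes = sel.select_genes_ica(ica_result, chosen,
                                         config.loading_threshold, labels)
        nmf_genes = sel.select_genes_nmf(nmf_result,
                                         config.nmf_gene_z_threshold,
                                         matrix, labels)
        write_table(ica_genes, out / "ica_genes.tsv")
        write_table(nmf_genes, out / "nmf_genes.tsv")
        written += [out / "ica_genes.tsv", out / "nmf_genes.tsv"]
        classes = sel.classify_samples(nmf_result.encodings)
        emit_df(pd.DataFrame({"sample_id": list(matrix.sample_ids),
                              "group": [labels.group_of(s) for s in matrix.sample_ids],
                              "metagene_class": classes}),
                "sample_classes.tsv")
        for j in range(nmf_result.k):
            rows, cols = sel.bicluster_sort(matrix, nmf_result, j)
            emit_df(pd.DataFrame({
                "position": np.arange(rows.size),
                "gene_id": [matrix.gene_ids[i] for i in rows]}),
                f"bicluster_factor{j + 1}_gene_order.tsv")
            emit_df(pd.DataFrame({
                "position": np.arange(cols.size),
                "sample_id": [matrix.sample_ids[i] for i in cols]}),
                f"bicluster_factor{j + 1}_sample_order.tsv")
        manifest["stages"].append(stage)

        stage = "integrate"
        report = sel.integrate_gene_sets(ica_genes, nmf_genes)
        (out / "overlap.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        written.append(out / "overlap.json")
        manifest["stages"].append(stage)
    except GeneFactorError as exc:
        raise StageError(stage, exc) from exc

    manifest["files"] = {p.name: _sha256(p) for p in sorted(written)}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("completed %d stages -> %s", len(manifest["stages"]), out)
    return manifest
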