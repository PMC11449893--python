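"""Single-driver execution of the full APA analysis pipeline.

Stages run in order: annotate (per-batch 3'UTR assignment and filter) →
integrate (snowball merge + requantification + re-annotation) → metrics
(PPUI, weighted 3'UTR length, per-cell summary, gene-level counts) →
markers (DEPAs, APA markers, optional switching pair) → celltyping
(consensus over supplied strategy labels, then APA-aware refinement of
unlabeled cells).  Every stage's outputs and a structured run log are
persisted under the output directory; a rerun with the same config and
seed reproduces every file byte for byte (the log carries no
timestamps for that reason).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import annotate as ann
from . import celltyping as ct
from . import integrate as intg
from . import io as io_mod
from . import markers as mk
from . import metrics as mt


class PipelineConfig(BaseModel):
    """Fully resolved pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    batch_dirs: list[str]
    gtf: str
    out_dir: str
    genome_fasta: Optional[str] = None
    labels_tsv: Optional[str] = None
    seed: int = 0

    utr_extension: int = 1000
    min_gene_count: int = 1
    target_sum: float = 1e4

    min_pct: float = 0.25
    logfc_threshold: float = 0.25
    alpha: float = 0.05
    pct_in_min: float = 0.20
    pct_out_max: float = 0.20
    metric_test_method: str = "fdr_bh"
    min_cells_metric: int = 10
    switch_groups: Optional[tuple[str, str]] = None
    group_by: str = "group"

    n_hvg: int = 200
    top_fraction: float = 0.05
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def stage_log(stage: str, **info) -> None:
        log_lines.append(json.dumps({"stage": stage, **info}, sort_keys=True))

    gtf_path = Path(config.gtf)
    if not gtf_path.exists():
        raise FileNotFoundError(f"gene model not found: {gtf_path}")
    for d in config.batch_dirs:
        if not Path(d).exists():
            raise FileNotFoundError(f"batch directory not found: {d}")

    (out / "config.yaml").write_text(
        yaml.safe_dump(json.loads(config.model_dump_json()), sort_keys=True)
    )

    model = ann.load_gene_model(str(gtf_path), extension=config.utr_extension)
    stage_log("load_gene_model", n_genes=len(model))

    # --- annotate: per-batch 3'UTR assignment and filter -----------------
    batches = {}
    for d in config.batch_dirs:
        batch_dir = Path(d)
        sm = io_mod.read_site_matrix(batch_dir)
        batch_id = str(sm.cells["batch"].iloc[0]) if "batch" in sm.cells else batch_dir.name
        annotated = ann.annotate_sites(sm.sites, model)
        filtered = ann.filter_3utr_matrix(sm, annotated)
        stage_log(
            "annotate",
            batch=batch_id,
            sites_in=sm.n_sites,
            sites_retained=filtered.n_sites,
            cells=sm.n_cells,
        )
        batches[batch_id] = filtered

    # --- integrate -------------------------------------------------------
    merged, merge_map = intg.merge_and_requantify(batches, model=model)
    merged_sites = merged.sites
    keep = merged_sites["region"].isin([ann.REGION_3UTR, ann.REGION_EXT])
    merged = merged.subset_sites(merged_sites.index[keep])
    stage_log(
        "integrate",
        n_merged_sites=merge_map.n_merged,
        n_retained_sites=merged.n_sites,
        n_cells=merged.n_cells,
        total_counts=merged.total_counts(),
    )
    integrate_dir = out / "integrated"
    io_mod.write_site_matrix(merged, integrate_dir)
    members = merge_map.members.set_index("merged_id")
    members.to_csv(integrate_dir / "members.tsv", sep="\t")
    io_mod.write_bed(merged.sites, integrate_dir / "merged_sites.bed")

    # --- metrics ----------------------------------------------------------
    index = mt.build_apa_index(merged.sites)
    ppui = mt.ppui(merged, index, min_gene_count=config.min_gene_count)
    lengths = mt.weighted_utr_length(merged, index, min_gene_count=config.min_gene_count)
    summary = mt.cell_ppui_summary(ppui)
    gene_mat = mt.gene_from_sites(merged)
    metrics_dir = out / "metrics"
    io_mod.write_metric_matrix(ppui, metrics_dir / "ppui.tsv")
    io_mod.write_metric_matrix(lengths, metrics_dir / "weighted_length.tsv")
    summary.rename_axis("cell_id").to_csv(metrics_dir / "cell_ppui_summary.tsv", sep="\t")
    stage_log(
        "metrics",
        n_apa_genes=len(index.apa_genes),
        n_genes=len(gene_mat.genes),
    )

    # --- markers ----------------------------------------------------------
    markers_dir = out / "markers"
    markers_dir.mkdir(exist_ok=True)
    depas = pd.DataFrame()
    apa_markers = pd.DataFrame()
    if config.group_by in merged.cells.columns:
        labels = merged.cells[config.group_by].astype(str)
        depas = mk.find_depas(
            merged,
            labels,
            min_pct=config.min_pct,
            logfc_threshold=config.logfc_threshold,
            alpha=config.alpha,
            pct_in_min=config.pct_in_min,
            pct_out_max=config.pct_out_max,
            target_sum=config.target_sum,
        )
        apa_markers = mk.find_apa_markers(
            ppui,
            labels,
            alpha=config.alpha,
            method=config.metric_test_method,
            min_cells=config.min_cells_metric,
        )
        depas.to_csv(markers_dir / "depas.tsv", sep="\t", index=False)
        apa_markers.to_csv(markers_dir / "apa_markers.tsv", sep="\t", index=False)
        if config.switch_groups is not None:
            ga, gb = config.switch_groups
            switching = mk.find_switching_genes(
                lengths,
                labels,
                ga,
                gb,
                alpha=config.alpha,
                method=config.metric_test_method,
                min_cells=config.min_cells_metric,
            )
            switching.to_csv(markers_dir / "switching_genes.tsv", sep="\t", index=False)
            stage_log(
                "switching",
                group_a=ga,
                group_b=gb,
                n_significant=int(switching.get("significant", pd.Series(dtype=bool)).sum()),
            )
        nonred = mk.nonredundant_apa_genes(
            depas, apa_markers, merged.sites["gene_id"]
        )
        io_mod.write_gmt(nonred, markers_dir / "nonredundant_apa_genes.gmt")
        stage_log(
            "markers",
            n_depa_tests=len(depas),
            n_depas_retained=int(depas["retained"].sum()) if "retained" in depas else 0,
            n_apa_marker_tests=len(apa_markers),
            n_apa_markers=int(apa_markers["significant"].sum())
            if "significant" in apa_markers
            else 0,
        )
    else:
        stage_log("markers", skipped=f"no '{config.group_by}' column in cell table")

    # --- celltyping -------------------------------------------------------
    if config.labels_tsv is not None:
        strategies = pd.read_csv(config.labels_tsv, sep="\t", index_col=0)
        strategies = strategies.reindex(merged.cells.index)
        consensus = ct.consensus_labels(strategies)
        labeled_mask = consensus["labeled"]
        expr = pd.DataFrame(
            ct.normalize_expression(gene_mat.counts, target_sum=config.target_sum),
            index=gene_mat.genes,
            columns=merged.cells.index,
        )
        final = consensus["consensus"].copy()
        provenance = pd.Series("consensus", index=final.index)
        if labeled_mask.any() and not labeled_mask.all() and not depas.empty:
            reference = ct.build_reference(
                expr.loc[:, labeled_mask.to_numpy()],
                consensus.loc[labeled_mask, "consensus"],
                n_hvg=config.n_hvg,
            )
            unl = final.index[~labeled_mask]
            gene_label = ct.pcc_annotate(expr[unl], reference)
            depa_sets = {
                g: list(sub["feature"])
                for g, sub in depas[depas["retained"]].groupby("group")
            }
            apa_sets = {
                g: list(sub["feature"])
                for g, sub in apa_markers[
                    apa_markers.get("significant", False) & (apa_markers["direction"] == "up")
                ].groupby("group")
            }
            site_values = pd.DataFrame(
                merged.counts.toarray(), index=merged.site_ids, columns=merged.cell_ids
            )[unl]
            depa_label = (
                ct.argmax_activity(
                    ct.auc_activity(
                        site_values, depa_sets, config.top_fraction, seed=config.seed
                    )
                )
                if depa_sets
                else pd.Series(None, index=unl, dtype=object)
            )
            apa_label = (
                ct.argmax_activity(
                    ct.auc_activity(
                        ppui.to_frame()[unl], apa_sets, config.top_fraction, seed=config.seed
                    )
                )
                if apa_sets
                else pd.Series(None, index=unl, dtype=object)
            )
            refined = ct.refine_unlabeled(gene_label, depa_label, apa_label)
            final.loc[unl] = refined["final"]
            provenance.loc[unl] = refined["provenance"]
        labels_out = pd.DataFrame(
            {"final": final, "provenance": provenance}
        ).rename_axis("cell_id")
        labels_out.to_csv(out / "cell_labels.tsv", sep="\t")
        stage_log(
            "celltyping",
            n_labeled=int(labeled_mask.sum()),
            n_unlabeled=int((~labeled_mask).sum()),
        )

    (out / "run_log.jsonl").write_text("\n".join(log_lines) + "\n")
    return out
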