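"""Shared fixtures: synthetic datasets at the scales the checks need.

All fixtures are session-scoped and deterministic (fixed seeds), so the
suite's heavy generation work happens once.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

import scapa_atlas as sa
from scapa_atlas import annotate as ann


@dataclass
class Run:
    """A generated dataset taken through annotation, merging and metrics."""

    config: sa.SynthConfig
    truth: sa.GroundTruth
    batches: dict
    gtf_path: str
    model: pd.DataFrame
    merged: sa.SiteMatrix          # requantified, re-annotated, 3'UTR-filtered
    merge_map: sa.MergeMap
    labels: pd.Series              # true cell types
    index: sa.ApaGeneIndex
    ppui: sa.MetricMatrix
    lengths: sa.MetricMatrix


def _run(config: sa.SynthConfig, tmp_factory) -> Run:
    truth, batches, gtf = sa.generate_dataset(config)
    gtf_path = tmp_factory.mktemp("model") / "genes.gtf"
    gtf_path.write_text(gtf)
    model = sa.load_gene_model(str(gtf_path))
    merged, merge_map = sa.merge_and_requantify(batches, model=model)
    keep = merged.sites["region"].isin([ann.REGION_3UTR, ann.REGION_EXT])
    merged = merged.subset_sites(merged.sites.index[keep])
    index = sa.build_apa_index(merged.sites)
    return Run(
        config=config,
        truth=truth,
        batches=batches,
        gtf_path=str(gtf_path),
        model=model,
        merged=merged,
        merge_map=merge_map,
        labels=merged.cells["cell_type"].astype(str),
        index=index,
        ppui=sa.ppui(merged, index),
        lengths=sa.weighted_utr_length(merged, index),
    )


@pytest.fixture(scope="session")
def small_run(tmp_path_factory) -> Run:
    """Small dataset exercising the extension and discard rules."""
    config = sa.SynthConfig(
        n_genes=60,
        cells_per_type_per_batch=30,
        extension_site_fraction=0.1,
        beyond_extension_fraction=0.1,
        seed=5,
    )
    return _run(config, tmp_path_factory)


@pytest.fixture(scope="session")
def marker_run(tmp_path_factory) -> Run:
    """Marker-recovery study: 4 types x ~200 cells, fold 4, pi 0.8 vs 0.3."""
    config = sa.SynthConfig(
        n_genes=400,
        cells_per_type_per_batch=67,
        seed=11,
    )
    return _run(config, tmp_path_factory)


@pytest.fixture(scope="session")
def refine_run(tmp_path_factory) -> Run:
    """Cell-typing refinement study: richer marker/shift planting."""
    config = sa.SynthConfig(
        n_genes=400,
        cells_per_type_per_batch=67,
        marker_gene_fraction=0.15,
        shift_gene_fraction=0.15,
        seed=21,
    )
    return _run(config, tmp_path_factory)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory) -> Run:
    """The generator's default study conditions (600 cells per type)."""
    return _run(sa.SynthConfig(), tmp_path_factory)
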