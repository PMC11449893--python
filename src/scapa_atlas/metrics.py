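"""Per-gene per-cell APA metrics.

Genes with at least two poly(A) sites in their (extended) 3'UTR are
3'UTR-APA genes.  For such a gene in cell s with site counts E_{i,s} and
site-to-stop-codon distances L_i, the two metrics are

    PPUI_s   = E_{p,s} / sum_i E_{i,s}          (p = proximal site, min L)
    L_s      = sum_i E_{i,s} L_i / sum_i E_{i,s}

PPUI is the proximal poly(A)-site usage index in [0,1] (high PPUI =
short 3'UTR); L_s is the expression-weighted relative 3'UTR length in
nt.  Both carry no pseudo-counts: a (gene, cell) entry is *missing*
(NaN) whenever the gene's total 3'UTR count in that cell is below the
defined-threshold (default 1), instead of being biased toward uniform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import GeneMatrix, MetricMatrix, SiteMatrix

log = logging.getLogger(__name__)


@dataclass
class ApaGeneIndex:
    """Per-gene ordered 3'UTR site list with distances.

    ``sites`` is a DataFrame (one row per gene-assigned site) with
    columns ``gene_id, L`` sorted by (gene, L, site id); ties in L are
    broken by lowest site id, which also fixes the proximal site
    deterministically.  ``is_apa_gene`` flags genes with >= 2 sites.
    """

    sites: pd.DataFrame
    is_apa_gene: pd.Series

    @property
    def apa_genes(self) -> pd.Index:
        return self.is_apa_gene.index[self.is_apa_gene]

    def sites_of(self, gene_id: str) -> pd.DataFrame:
        return self.sites[self.sites["gene_id"] == gene_id]

    def proximal_site(self, gene_id: str) -> str:
        return self.sites_of(gene_id).index[0]


def build_apa_index(annotated_sites: pd.DataFrame) -> ApaGeneIndex:
    """Group gene-assigned sites by gene, ordered proximal to distal.

    ``annotated_sites`` must carry ``gene_id`` and ``L`` columns (as
    produced by annotation); unassigned sites are ignored.
    """
    assigned = annotated_sites.dropna(subset=["gene_id"]).copy()
    assigned["L"] = assigned["L"].astype(int)
    assigned = assigned.rename_axis("site_id").reset_index()
    assigned = assigned.sort_values(
        ["gene_id", "L", "site_id"], kind="mergesort", ignore_index=True
    ).set_index("site_id")
    n_sites = assigned.groupby("gene_id").size()
    is_apa = n_sites >= 2
    is_apa.name = "is_apa_gene"
    return ApaGeneIndex(sites=assigned[["gene_id", "L"]], is_apa_gene=is_apa)


def _gene_site_operators(matrix: SiteMatrix, index: ApaGeneIndex):
    """Sparse gene×site aggregation operators restricted to APA genes.

    Returns (genes, S_total, S_prox, S_len): indicator of all member
    sites, indicator of the proximal site, and L-weighted indicator.
    """
    genes = index.apa_genes.sort_values()
    gene_pos = pd.Series(np.arange(len(genes)), index=genes)
    sites = index.sites[index.sites["gene_id"].isin(genes)]
    present = sites.index.intersection(matrix.site_ids)
    sites = sites.loc[present]
    site_pos = matrix.site_ids.get_indexer(sites.index)
    rows = gene_pos[sites["gene_id"].to_numpy()].to_numpy()
    shape = (len(genes), matrix.n_sites)
    ones = np.ones(len(sites))
    S_total = sp.csr_matrix((ones, (rows, site_pos)), shape=shape)
    S_len = sp.csr_matrix((sites["L"].to_numpy(float), (rows, site_pos)), shape=shape)
    # Proximal = first site (min L, ties by id) among those present in the
    # matrix for each gene.
    first = sites.rename_axis("site_id").reset_index().groupby("gene_id", sort=False).head(1)
    prox_rows = gene_pos[first["gene_id"].to_numpy()].to_numpy()
    prox_cols = matrix.site_ids.get_indexer(first["site_id"])
    S_prox = sp.csr_matrix(
        (np.ones(len(first)), (prox_rows, prox_cols)), shape=shape
    )
    return genes, S_total, S_prox, S_len


def ppui(matrix: SiteMatrix, index: ApaGeneIndex, min_gene_count: int = 1) -> MetricMatrix:
    """Proximal poly(A)-site usage index per APA gene per cell.

    Entries are proximal counts over total 3'UTR counts; NaN where the
    gene's total count in the cell is below ``min_gene_count``.
    """
    genes, S_total, S_prox, _ = _gene_site_operators(matrix, index)
    totals = np.asarray((S_total @ matrix.counts).todense(), dtype=float)
    prox = np.asarray((S_prox @ matrix.counts).todense(), dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(totals >= max(min_gene_count, 1), prox / totals, np.nan)
    return MetricMatrix(
        values=values,
        genes=genes,
        cells=matrix.cell_ids,
        kind="ppui",
        params={"min_gene_count": min_gene_count},
    )


def weighted_utr_length(
    matrix: SiteMatrix, index: ApaGeneIndex, min_gene_count: int = 1
) -> MetricMatrix:
    """Expression-weighted relative 3'UTR length per APA gene per cell."""
    genes, S_total, _, S_len = _gene_site_operators(matrix, index)
    totals = np.asarray((S_total @ matrix.counts).todense(), dtype=float)
    weighted = np.asarray((S_len @ matrix.counts).todense(), dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(totals >= max(min_gene_count, 1), weighted / totals, np.nan)
    return MetricMatrix(
        values=values,
        genes=genes,
        cells=matrix.cell_ids,
        kind="weighted_length",
        params={"min_gene_count": min_gene_count},
    )


def gene_from_sites(matrix: SiteMatrix) -> GeneMatrix:
    """Sum each gene's site counts into a gene × cell count matrix.

    Sites without a gene assignment are excluded (their count is logged).
    Genes whose sites were all filtered out are absent from the output.
    """
    sites = matrix.sites
    if "gene_id" not in sites.columns:
        raise ValueError("sites must be annotated with gene_id")
    assigned = sites.dropna(subset=["gene_id"])
    n_dropped = len(sites) - len(assigned)
    if n_dropped:
        log.info("gene_from_sites: %d unassigned site(s) excluded", n_dropped)
    genes = pd.Index(sorted(assigned["gene_id"].unique()), name="gene_id")
    gene_pos = pd.Series(np.arange(len(genes)), index=genes)
    rows = gene_pos[assigned["gene_id"].to_numpy()].to_numpy()
    cols = matrix.site_ids.get_indexer(assigned.index)
    indicator = sp.csr_matrix(
        (np.ones(len(assigned), dtype=np.int64), (rows, cols)),
        shape=(len(genes), matrix.n_sites),
    )
    return GeneMatrix(
        counts=indicator @ matrix.counts, genes=genes, cells=matrix.cells.copy()
    )


def cell_ppui_summary(metric: MetricMatrix, weighted: bool = False) -> pd.Series:
    """Summarize per-cell proximal usage: mean PPUI over defined genes.

    The default is the unweighted mean of the cell's defined PPUI
    entries (NaN for cells with none).  ``weighted=True`` is available
    but changes the question subtly: genes then contribute by coverage.
    """
    if metric.kind != "ppui":
        raise ValueError("cell_ppui_summary expects a PPUI matrix")
    if weighted:
        raise NotImplementedError(
            "count-weighted summary requires the originating SiteMatrix; "
            "use ppui totals externally"
        )
    defined = np.sum(~np.isnan(metric.values), axis=0)
    totals = np.nansum(metric.values, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(defined > 0, totals / defined, np.nan)
    return pd.Series(values, index=metric.cells, name="ppui_summary")
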