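"""Core in-memory containers shared across the pipeline.

The toolkit follows the tidy single-cell convention of sparse count
matrices with parallel metadata tables.  A :class:`SiteMatrix` holds
poly(A)-site read counts (sites on rows, cells on columns — the layout of
a 3'-tag poly(A)-site expression matrix), a site table describing each
peak as a stranded genomic interval, and a cell table with at least a
batch assignment.  A :class:`MetricMatrix` holds a dense gene × cell APA
metric (PPUI or weighted 3'UTR length) with explicit missingness as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Required columns of a site table.  ``start``/``end`` are 0-based
#: half-open genomic coordinates of the peak interval.
SITE_COLUMNS = ("chrom", "start", "end", "strand")

#: Columns added by annotation.  ``coord`` is the representative cleavage
#: position (strand-aware distal end of the peak); ``L`` is its distance
#: in nt to the assigned gene's stop codon.
ANNOT_COLUMNS = ("coord", "gene_id", "region", "L")


class SiteMatrixError(ValueError):
    """Structural problem in a SiteMatrix (shape/id mismatch, bad counts)."""


@dataclass
class SiteMatrix:
    """Sparse poly(A)-site counts with site and cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, sites × cells.
    sites
        DataFrame indexed by unique site id with at least
        ``chrom, start, end, strand`` columns.
    cells
        DataFrame indexed by unique cell id with at least a ``batch``
        column; an optional ``group`` column carries cell-type labels.
    """

    counts: sp.spmatrix
    sites: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.sites), len(self.cells)):
            raise SiteMatrixError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sites)} sites x {len(self.cells)} cells"
            )
        if not self.sites.index.is_unique:
            raise SiteMatrixError("site ids are not unique")
        if not self.cells.index.is_unique:
            raise SiteMatrixError("cell ids are not unique")
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise SiteMatrixError(f"site table lacks columns: {missing}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise SiteMatrixError("counts must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def site_ids(self) -> pd.Index:
        return self.sites.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    def total_counts(self) -> int:
        return int(self.counts.sum())

    def subset_sites(self, site_ids) -> "SiteMatrix":
        """Return a new matrix restricted to ``site_ids`` (order preserved)."""
        idx = self.sites.index.get_indexer(pd.Index(site_ids))
        if (idx < 0).any():
            bad = list(pd.Index(site_ids)[idx < 0][:5])
            raise SiteMatrixError(f"unknown site ids: {bad}")
        return SiteMatrix(
            counts=self.counts[idx],
            sites=self.sites.iloc[idx].copy(),
            cells=self.cells.copy(),
        )

    def with_sites(self, sites: pd.DataFrame) -> "SiteMatrix":
        """Replace the site table (same index, e.g. after annotation)."""
        if not sites.index.equals(self.sites.index):
            raise SiteMatrixError("replacement site table has a different index")
        return replace(self, sites=sites.copy())


@dataclass
class MetricMatrix:
    """Dense gene × cell APA metric with explicit missingness (NaN).

    ``kind`` is ``"ppui"`` (proximal poly(A)-site usage index, in [0,1];
    high = short 3'UTR) or ``"weighted_length"`` (expression-weighted
    distance of the gene's sites to its stop codon, in nt).
    """

    values: np.ndarray
    genes: pd.Index
    cells: pd.Index
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("metric values shape does not match gene/cell index")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)


@dataclass
class GeneMatrix:
    """Gene × cell counts obtained by summing a gene's site counts."""

    counts: sp.spmatrix
    genes: pd.Index
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError("gene counts shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.genes, columns=self.cells.index
        )
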