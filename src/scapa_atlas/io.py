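"""On-disk formats: MTX site matrices, TSV tables, BED, GMT.

A site matrix directory holds ``matrix.mtx`` (MatrixMarket integer
sparse, sites on rows, cells on columns), ``sites.tsv`` (id, chrom,
start, end, strand, plus any annotation columns; coordinates 0-based
half-open, BED-compatible) and ``cells.tsv`` (cell id, batch, optional
group).  TSVs are tab-delimited UTF-8 with a header row.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import SiteMatrix

log = logging.getLogger(__name__)


def write_site_matrix(matrix: SiteMatrix, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        out / "matrix.mtx", sp.coo_matrix(matrix.counts), field="integer"
    )
    matrix.sites.rename_axis("site_id").to_csv(out / "sites.tsv", sep="\t")
    matrix.cells.rename_axis("cell_id").to_csv(out / "cells.tsv", sep="\t")
    return out


def read_site_matrix(in_dir: str | Path) -> SiteMatrix:
    """Read a matrix directory; round-trips :func:`write_site_matrix` exactly."""
    d = Path(in_dir)
    for name in ("matrix.mtx", "sites.tsv", "cells.tsv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"{d} lacks {name}")
    counts = sp.csr_matrix(scipy.io.mmread(d / "matrix.mtx")).astype(np.int64)
    sites = pd.read_csv(d / "sites.tsv", sep="\t", index_col="site_id")
    cells = pd.read_csv(d / "cells.tsv", sep="\t", index_col="cell_id")
    if counts.shape[0] != len(sites):
        raise ValueError(
            f"{d}: matrix has {counts.shape[0]} rows but sites.tsv {len(sites)}"
        )
    if counts.shape[1] != len(cells):
        raise ValueError(
            f"{d}: matrix has {counts.shape[1]} columns but cells.tsv {len(cells)}"
        )
    if len(cells) == 0:
        raise ValueError(f"{d}: matrix has zero cells")
    return SiteMatrix(counts=counts, sites=sites, cells=cells)


def write_metric_matrix(metric, out_path: str | Path) -> Path:
    """Dense TSV of a MetricMatrix (NaN marks missing entries)."""
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    metric.to_frame().rename_axis("gene_id").to_csv(out, sep="\t")
    return out


def write_bed(sites: pd.DataFrame, out_path: str | Path) -> Path:
    """BED6 export of (annotated) sites: name = site id, score = 0."""
    out = Path(out_path)
    bed = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["start"],
            "end": sites["end"],
            "name": sites.index,
            "score": 0,
            "strand": sites["strand"],
        }
    )
    bed.to_csv(out, sep="\t", header=False, index=False)
    return out


def write_gmt(sets: Mapping[str, Sequence[str]], out_path: str | Path) -> Path:
    """Feature sets in GMT format (name, description, members...)."""
    out = Path(out_path)
    with open(out, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(map(str, sets[name])))
            fh.write(f"{name}\t{name}\t{members}\n")
    return out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets
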