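"""Cross-batch integration of poly(A)-site peaks ("snowball" merge).

Peak calling is done per batch, so the peak interval of one biological
poly(A) site differs slightly between batches.  Integration sorts all
peaks by start position within (chromosome, strand), sweeps once, and
combines every peak that intersects the growing cluster — transitively,
so chains of pairwise-overlapping peaks collapse into one merged site.
"Intersecting" means sharing at least one base: half-open intervals that
merely touch stay separate.  The merged site's representative coordinate
is the most distal peak end in the direction of transcription.  Each
batch is then requantified against the merged site list by summing each
cell's counts over the member peaks of its own batch.

Batch-effect correction of embeddings (e.g. Harmony) is out of scope:
downstream statistics operate on counts and ratios; the merged matrix
carries batch labels for any external embedding tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotate import annotate_sites
from .containers import SiteMatrix

log = logging.getLogger(__name__)

#: Merged intervals wider than this are logged (not rejected): the
#: snowball imposes no width cap, but very wide clusters merit a look.
WIDTH_WARN_NT = 1000


@dataclass
class MergeMap:
    """Result of a snowball merge.

    ``merged`` is a DataFrame indexed by deterministic merged id
    (``chrom:strand:start-end``) with columns ``chrom, start, end,
    strand, coord, n_members``; ``members`` maps every source peak
    (``batch``, ``site_id``) to its ``merged_id``.
    """

    merged: pd.DataFrame
    members: pd.DataFrame

    @property
    def n_merged(self) -> int:
        return len(self.merged)

    def members_of(self, merged_id: str) -> pd.DataFrame:
        return self.members[self.members["merged_id"] == merged_id]


def _pool_sites(batch_sites: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    frames = []
    for batch, sites in batch_sites.items():
        bad = sites.index[sites["start"] >= sites["end"]]
        if len(bad):
            raise ValueError(
                f"batch {batch}: malformed intervals (start >= end) for sites "
                f"{list(bad[:5])}"
            )
        f = sites[["chrom", "start", "end", "strand"]].copy()
        f["batch"] = batch
        f["site_id"] = sites.index
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def snowball_merge(batch_sites: Mapping[str, pd.DataFrame]) -> MergeMap:
    """Merge per-batch peak lists into one unified poly(A)-site list.

    ``batch_sites`` maps batch id → site table (indexed by site id, with
    ``chrom, start, end, strand``).  The result is independent of batch
    order and of within-batch row order.
    """
    pool = _pool_sites(batch_sites)
    # Stable global order; sorting by start is the sweep precondition.
    pool = pool.sort_values(
        ["chrom", "strand", "start", "end", "batch", "site_id"],
        kind="mergesort",
        ignore_index=True,
    )
    cluster_id = np.empty(len(pool), dtype=np.int64)
    n_clusters = 0
    for (_, _), idx in pool.groupby(["chrom", "strand"], sort=True).indices.items():
        starts = pool["start"].to_numpy()[idx]
        ends = pool["end"].to_numpy()[idx]
        # Sweep: a new cluster starts whenever the next peak begins at or
        # past the running maximum end (touching does not merge).
        run_max = np.maximum.accumulate(ends)
        new_cluster = np.ones(len(idx), dtype=bool)
        new_cluster[1:] = starts[1:] >= run_max[:-1]
        cluster_id[idx] = n_clusters + np.cumsum(new_cluster) - 1
        n_clusters += int(new_cluster.sum())
    pool["cluster"] = cluster_id

    agg = pool.groupby("cluster").agg(
        chrom=("chrom", "first"),
        strand=("strand", "first"),
        start=("start", "min"),
        end=("end", "max"),
        n_members=("site_id", "size"),
    )
    agg["coord"] = np.where(agg["strand"] == "+", agg["end"] - 1, agg["start"])
    agg["merged_id"] = (
        agg["chrom"].astype(str)
        + ":"
        + agg["strand"]
        + ":"
        + agg["start"].astype(str)
        + "-"
        + agg["end"].astype(str)
    )
    wide = agg[agg["end"] - agg["start"] > WIDTH_WARN_NT]
    if len(wide):
        log.warning(
            "%d merged site(s) wider than %d nt (widest %d nt)",
            len(wide),
            WIDTH_WARN_NT,
            int((wide["end"] - wide["start"]).max()),
        )
    merged = (
        agg.reset_index(drop=True)
        .set_index("merged_id")[["chrom", "start", "end", "strand", "coord", "n_members"]]
        .sort_index()
    )
    members = pool[["batch", "site_id", "cluster"]].copy()
    members["merged_id"] = agg.loc[members["cluster"], "merged_id"].to_numpy()
    members = members.drop(columns="cluster").sort_values(
        ["batch", "site_id"], ignore_index=True
    )
    log.info(
        "snowball merge: %d source peaks from %d batches -> %d merged sites",
        len(pool),
        len(batch_sites),
        len(merged),
    )
    return MergeMap(merged=merged, members=members)


def requantify(
    merge_map: MergeMap, batches: Mapping[str, SiteMatrix]
) -> SiteMatrix:
    """Recount every cell against the merged site list.

    The merged count of (site, cell) is the sum of the cell's counts
    over the member peaks contributed by the cell's own batch; cells of
    all batches are concatenated (batch recorded in the cell table).
    Cell ids are only required to be unique within a batch: if plain
    concatenation would collide, every cell id is prefixed with
    ``<batch>:``.  The grand total of counts is conserved exactly.
    """
    merged_ids = merge_map.merged.index
    merged_pos = pd.Series(np.arange(len(merged_ids)), index=merged_ids)
    blocks = []
    cell_frames = []
    for batch, sm in batches.items():
        mem = merge_map.members[merge_map.members["batch"] == batch]
        lookup = pd.Series(mem["merged_id"].to_numpy(), index=mem["site_id"])
        missing = sm.site_ids.difference(lookup.index)
        if len(missing):
            raise ValueError(
                f"batch {batch}: {len(missing)} source site(s) absent from the "
                f"merge map, e.g. {list(missing[:5])}"
            )
        rows = merged_pos[lookup[sm.site_ids].to_numpy()].to_numpy()
        indicator = sp.csr_matrix(
            (np.ones(sm.n_sites, dtype=np.int64), (rows, np.arange(sm.n_sites))),
            shape=(len(merged_ids), sm.n_sites),
        )
        blocks.append(indicator @ sm.counts)
        cells = sm.cells.copy()
        cells["batch"] = batch
        cell_frames.append(cells)
    counts = sp.hstack(blocks, format="csr")
    cells = pd.concat(cell_frames)
    if not cells.index.is_unique:
        cells.index = pd.Index(
            [f"{b}:{c}" for b, c in zip(cells["batch"], cells.index)],
            name=cells.index.name,
        )
    return SiteMatrix(counts=counts, sites=merge_map.merged.copy(), cells=cells)


def reannotate_merged(merge_map: MergeMap, model: pd.DataFrame) -> pd.DataFrame:
    """Re-annotate merged peak ranges against the gene model.

    Gene, region and stop-codon distance are recomputed from the merged
    interval's representative coordinate, not inherited from any source
    batch.
    """
    return annotate_sites(merge_map.merged, model)


def merge_and_requantify(
    batches: Mapping[str, SiteMatrix], model: pd.DataFrame | None = None
):
    """Convenience wrapper: snowball merge, requantify, optionally re-annotate.

    Returns ``(merged_matrix, merge_map)``; if ``model`` is given the
    merged matrix's site table carries fresh annotation columns.
    """
    merge_map = snowball_merge({b: sm.sites for b, sm in batches.items()})
    merged = requantify(merge_map, batches)
    if model is not None:
        merged = merged.with_sites(reannotate_merged(merge_map, model))
    return merged, merge_map
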