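"""Consensus cell-type annotation and APA-aware refinement.

Several independent annotation strategies (reference correlation,
index-of-cell-identity, clustering + known markers, ...) each propose a
cell-type label per cell; cells on which at least two strategies agree
are *labeled*, the rest *unlabeled*.  Labeled cells define a reference
expression profile (mean normalized expression of the top highly
variable genes per type).  Unlabeled cells are then re-annotated three
ways — Pearson correlation to the reference profile, and AUC-based
activity of per-type DEPA site sets and APA-marker gene sets — and the
majority of the three wins; if all three disagree, the DEPA-based label
is used.

The AUC activity of a feature set in a cell is the area under the
set-recovery curve across the cell's expression-ranked features,
evaluated within the top ``top_fraction`` of ranks and normalized to
its maximum attainable value, so it is a rank statistic in [0,1]
invariant to monotone transforms of the cell's expression vector.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger(__name__)

UNLABELED = "unlabeled"


def consensus_labels(strategies: pd.DataFrame) -> pd.DataFrame:
    """Combine per-strategy label columns into a consensus label.

    ``strategies`` is cells × strategies; missing votes are NaN/None.
    A cell gets the modal label when its support is >= 2; ties at the
    top support (e.g. A,A,B,B) and support-1 patterns yield
    ``unlabeled``.  Returns a DataFrame with the strategy columns, a
    ``consensus`` column and a ``labeled`` flag.
    """
    if strategies.shape[1] < 2:
        raise ValueError("consensus requires at least two strategies")
    if not strategies.index.is_unique:
        raise ValueError("duplicated cell ids in strategy table")
    out = strategies.copy()
    consensus = []
    for _, votes in strategies.iterrows():
        counts = votes.dropna().value_counts()
        if len(counts) and counts.iloc[0] >= 2:
            top = counts[counts == counts.iloc[0]]
            consensus.append(top.index[0] if len(top) == 1 else UNLABELED)
        else:
            consensus.append(UNLABELED)
    out["consensus"] = consensus
    out["labeled"] = out["consensus"] != UNLABELED
    log.info(
        "consensus: %d/%d cells labeled by >=2-strategy agreement",
        int(out["labeled"].sum()),
        len(out),
    )
    return out


def normalize_expression(counts: sp.spmatrix, target_sum: float = 1e4) -> np.ndarray:
    """Dense log-normalized gene × cell expression (scale + log1p)."""
    from .markers import normalize_log1p

    return np.asarray(normalize_log1p(counts, target_sum=target_sum).todense())


def select_hvgs(expr: pd.DataFrame, n_hvg: int = 200) -> pd.Index:
    """Top-``n_hvg`` genes by variance of log-normalized expression.

    A single global ranking across all (labeled) cells; per-type
    rankings are a documented option of :func:`build_reference`.
    """
    variances = expr.var(axis=1)
    return variances.sort_values(ascending=False, kind="mergesort").index[:n_hvg]


def build_reference(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_hvg: int = 200,
    per_type: bool = False,
) -> pd.DataFrame:
    """Mean expression of top HVGs per cell type (genes × types).

    ``expr`` is log-normalized genes × cells restricted to labeled
    cells; ``labels`` gives each cell's type.  With ``per_type=True``
    the HVG union of per-type top-``n_hvg`` rankings is used instead of
    one global ranking.  Types without cells are omitted with a warning.
    """
    labels = labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("labels must cover every cell of the expression matrix")
    if per_type:
        hvgs = pd.Index([])
        for t in sorted(labels.unique()):
            sub = expr.loc[:, (labels == t).to_numpy()]
            hvgs = hvgs.union(select_hvgs(sub, n_hvg))
    else:
        hvgs = select_hvgs(expr, n_hvg)
    profiles = {}
    for t in sorted(labels.unique()):
        mask = (labels == t).to_numpy()
        if not mask.any():
            log.warning("cell type %s has no labeled cells; omitted from reference", t)
            continue
        profiles[t] = expr.loc[hvgs, mask].mean(axis=1)
    if not profiles:
        raise ValueError("no cell type has labeled cells")
    return pd.DataFrame(profiles, index=hvgs)


def pcc_annotate(expr: pd.DataFrame, reference: pd.DataFrame) -> pd.Series:
    """Label each cell by its best-correlated reference profile.

    Pearson correlation on the gene set shared between ``expr`` (genes ×
    cells) and ``reference`` (genes × types); cells or profiles with zero
    variance get no label (NaN).
    """
    if reference.shape[1] < 2:
        raise ValueError("reference must contain at least two cell types")
    shared = expr.index.intersection(reference.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between expression matrix and reference")
    X = expr.loc[shared].to_numpy(float)  # genes x cells
    R = reference.loc[shared].to_numpy(float)  # genes x types
    Xc = X - X.mean(axis=0, keepdims=True)
    Rc = R - R.mean(axis=0, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=0))
    rs = np.sqrt((Rc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Rc.T @ Xc) / np.outer(rs, xs)  # types x cells
    best = np.full(X.shape[1], None, dtype=object)
    valid = np.isfinite(corr).any(axis=0)
    if valid.any():
        best_idx = np.nanargmax(np.where(np.isfinite(corr), corr, -np.inf), axis=0)
        best[valid] = reference.columns.to_numpy()[best_idx[valid]]
    return pd.Series(best, index=expr.columns, name="gene_pcc")


def auc_activity(
    values: pd.DataFrame,
    sets: Mapping[str, Sequence[str]],
    top_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC set-activity score of each feature set in each cell.

    ``values`` is features × cells (counts, normalized expression, or a
    metric such as PPUI — only ranks matter; NaN ranks last).  Features
    are ranked by decreasing value per cell with ties broken by a seeded
    random permutation; the activity of a set is the area under its
    recovery curve within the top ``ceil(top_fraction * n_features)``
    ranks, normalized by the maximal attainable area.  Returns a sets ×
    cells DataFrame in [0, 1].
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    n_features = len(values.index)
    window = int(np.ceil(top_fraction * n_features))
    rng = np.random.default_rng(seed)
    tie_break = rng.permutation(n_features)
    X = values.to_numpy(float)
    X = np.where(np.isnan(X), -np.inf, X)

    set_masks = {}
    for name, members in sets.items():
        mask = values.index.isin(pd.Index(members))
        if not mask.any():
            log.warning("set %s has no features in the matrix; activity 0", name)
        set_masks[name] = mask

    # Max area: all hits packed at the top of the window.
    activities = np.zeros((len(set_masks), X.shape[1]))
    order_cols = np.lexsort((tie_break[:, None].repeat(X.shape[1], 1), -X), axis=0)
    for j in range(X.shape[1]):
        top = order_cols[:window, j]
        for si, (name, mask) in enumerate(set_masks.items()):
            s = int(mask.sum())
            if s == 0:
                continue
            hits = mask[top]
            cum = np.cumsum(hits)
            area = cum.sum()
            max_cum = np.minimum(np.arange(1, window + 1), min(s, window))
            max_area = max_cum.sum()
            activities[si, j] = area / max_area if max_area else 0.0
    return pd.DataFrame(activities, index=list(set_masks), columns=values.columns)


def argmax_activity(activity: pd.DataFrame) -> pd.Series:
    """Per-cell label = set with highest activity (ties: first set name)."""
    arr = activity.to_numpy()
    labels = activity.index.to_numpy()[np.argmax(arr, axis=0)]
    out = pd.Series(labels, index=activity.columns, dtype=object)
    out[arr.max(axis=0) <= 0] = None
    return out


def refine_unlabeled(
    gene_label: pd.Series, depa_label: pd.Series, apa_label: pd.Series
) -> pd.DataFrame:
    """Majority vote of the three re-annotations, DEPA breaking ties.

    For each cell: the label occurring most often among the
    gene-expression, DEPA-set and APA-marker-set annotations wins; if
    all three differ, the DEPA-based label is used.  Missing votes are
    ignored (a lone remaining vote wins; all missing -> unlabeled).
    Returns a DataFrame with ``final`` and ``provenance`` columns.
    """
    idx = gene_label.index
    if not (depa_label.index.equals(idx) and apa_label.index.equals(idx)):
        raise ValueError("the three label vectors must share one cell index")
    finals, prov = [], []
    for cell in idx:
        votes = {
            "gene_pcc": gene_label[cell],
            "depa_auc": depa_label[cell],
            "apa_auc": apa_label[cell],
        }
        votes = {k: v for k, v in votes.items() if v is not None and not pd.isna(v)}
        if not votes:
            finals.append(UNLABELED)
            prov.append("none")
            continue
        counts = pd.Series(list(votes.values())).value_counts()
        if counts.iloc[0] >= 2:
            finals.append(counts.index[0])
            prov.append("majority")
        elif "depa_auc" in votes:
            finals.append(votes["depa_auc"])
            prov.append("depa_tiebreak")
        else:
            # No DEPA vote to break the tie; fall back to the gene label.
            finals.append(votes.get("gene_pcc", next(iter(votes.values()))))
            prov.append("gene_pcc")
    return pd.DataFrame({"final": finals, "provenance": prov}, index=idx)


def relabel_low_support(
    labels: pd.DataFrame,
    target: str,
    fallback: str,
    min_support: int = 2,
) -> pd.Series:
    """Re-assign a designated label lacking multi-source support.

    Cells whose ``target`` label is carried by fewer than
    ``min_support`` of the available label sources (columns) are
    re-assigned ``fallback``.  Mirrors the re-annotation of weakly
    supported quiescent-center calls to stem-cell-niche.
    """
    support = (labels == target).sum(axis=1)
    final = labels.iloc[:, -1].copy()
    final[(final == target) & (support < min_support)] = fallback
    return final


def filter_expression_matrix(
    counts: pd.DataFrame,
    stage: str = "per_batch",
    min_genes_per_cell: int | None = None,
    min_cells_per_gene: int | None = None,
    exclude_genes: Sequence[str] = (),
) -> pd.DataFrame:
    """Iterative gene/cell detection filter to a fixed point.

    ``stage='per_batch'`` keeps cells with >= 200 expressed genes and
    genes expressed in >= 3 cells; ``stage='combined'`` uses 500 / 5.
    Both thresholds can be overridden.  ``exclude_genes`` (organellar or
    protoplast-affected genes) are dropped first.  Raises if the fixed
    point is empty.
    """
    defaults = {"per_batch": (200, 3), "combined": (500, 5)}
    if stage not in defaults:
        raise ValueError("stage must be 'per_batch' or 'combined'")
    g_min, c_min = defaults[stage]
    if min_genes_per_cell is not None:
        g_min = min_genes_per_cell
    if min_cells_per_gene is not None:
        c_min = min_cells_per_gene
    out = counts.drop(index=[g for g in exclude_genes if g in counts.index])
    while True:
        detected = out > 0
        keep_cells = detected.sum(axis=0) >= g_min
        keep_genes = detected.sum(axis=1) >= c_min
        if keep_cells.all() and keep_genes.all():
            break
        out = out.loc[keep_genes, keep_cells]
        if out.empty:
            raise ValueError("expression filter removed every gene or cell")
    log.info(
        "expression filter (%s): %d genes x %d cells retained of %d x %d",
        stage,
        out.shape[0],
        out.shape[1],
        counts.shape[0],
        counts.shape[1],
    )
    return out
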