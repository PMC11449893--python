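"""Detection of the three APA marker classes.

DEPAs (differentially expressed poly(A) sites) are found Seurat-style on
library-size-normalized, log1p site counts: one-vs-rest Wilcoxon
rank-sum per cell group, candidates prefiltered by detection fraction
(min.pct 0.25) and |logFC| >= 0.25, p-values Bonferroni-adjusted over
the tests actually performed, and the final group-enriched set
additionally requires detection in > 20% of the target group and < 20%
of the remaining cells, up direction only.

APA markers test the per-gene PPUI values between groups; APA switching
genes test the weighted 3'UTR length between two named groups, with the
direction (lengthening/shortening) given by the difference of group
means.  Both use BH FDR by default (configurable to Bonferroni).

All detectors emit one tidy MarkerRecord row per (feature, group) with a
fixed column order.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._stats import rank_sum_test
from .containers import MetricMatrix, SiteMatrix

log = logging.getLogger(__name__)

MARKER_COLUMNS = [
    "feature",
    "kind",
    "group",
    "contrast",
    "statistic",
    "p_raw",
    "p_adj",
    "effect",
    "pct_in",
    "pct_out",
    "direction",
]


def normalize_log1p(counts: sp.spmatrix, target_sum: float = 1e4) -> sp.csr_matrix:
    """Per-cell library-size scaling to ``target_sum`` followed by log1p.

    ``counts`` is features × cells.  Cells with zero total are left at
    zero.  This replaces the invoked tool's default normalization with a
    dependency-free, exactly reproducible equivalent.
    """
    counts = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    scale = np.divide(
        target_sum, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0
    )
    normalized = counts @ sp.diags(scale)
    normalized.data = np.log1p(normalized.data)
    return sp.csr_matrix(normalized)


def _adjust(p_raw: np.ndarray, method: str) -> np.ndarray:
    """Bonferroni over tests performed, or BH FDR (statsmodels)."""
    p_raw = np.asarray(p_raw, dtype=float)
    if len(p_raw) == 0:
        return p_raw
    if method == "bonferroni":
        return np.minimum(1.0, p_raw * len(p_raw))
    if method == "fdr_bh":
        from statsmodels.stats.multitest import multipletests

        return multipletests(p_raw, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method: {method}")


def _check_labels(labels: pd.Series, cells: pd.Index) -> pd.Series:
    labels = labels.reindex(cells)
    if labels.isna().any():
        raise ValueError("every cell needs a group label for marker detection")
    return labels.astype(str)


def find_depas(
    matrix: SiteMatrix,
    labels: pd.Series,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    alpha: float = 0.05,
    pct_in_min: float = 0.20,
    pct_out_max: float = 0.20,
    min_cells: int = 3,
    target_sum: float = 1e4,
) -> pd.DataFrame:
    """One-vs-rest differentially expressed poly(A) sites per group.

    Returns a tidy marker table with a boolean ``retained`` column: the
    final DEPA set are the up-regulated candidates with Bonferroni
    p < ``alpha``, detection > ``pct_in_min`` in the target group and
    < ``pct_out_max`` outside it.
    """
    labels = _check_labels(labels, matrix.cell_ids)
    norm = normalize_log1p(matrix.counts, target_sum=target_sum)
    dense = np.asarray(norm.todense())
    detected = np.asarray((matrix.counts > 0).todense())
    expm1 = np.expm1(dense)

    rows = []
    groups = sorted(labels.unique())
    for group in groups:
        in_mask = (labels == group).to_numpy()
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < min_cells or n_out < min_cells:
            log.warning("group %s skipped: fewer than %d cells on one side", group, min_cells)
            continue
        pct_in = detected[:, in_mask].mean(axis=1)
        pct_out = detected[:, ~in_mask].mean(axis=1)
        # Seurat-style logFC: natural log of (mean de-logged + 1) ratio.
        mean_in = expm1[:, in_mask].mean(axis=1)
        mean_out = expm1[:, ~in_mask].mean(axis=1)
        logfc = np.log(mean_in + 1.0) - np.log(mean_out + 1.0)
        candidate = (np.maximum(pct_in, pct_out) >= min_pct) & (
            np.abs(logfc) >= logfc_threshold
        )
        for i in np.nonzero(candidate)[0]:
            u, p = rank_sum_test(dense[i, in_mask], dense[i, ~in_mask])
            rows.append(
                dict(
                    feature=matrix.site_ids[i],
                    kind="DEPA",
                    group=group,
                    contrast="one_vs_rest",
                    statistic=u,
                    p_raw=p,
                    effect=logfc[i],
                    pct_in=pct_in[i],
                    pct_out=pct_out[i],
                )
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(columns=MARKER_COLUMNS + ["retained"])
    table["p_adj"] = _adjust(table["p_raw"].to_numpy(), "bonferroni")
    table["direction"] = np.where(table["effect"] > 0, "up", "down")
    table["retained"] = (
        (table["direction"] == "up")
        & (table["p_adj"] < alpha)
        & (table["pct_in"] > pct_in_min)
        & (table["pct_out"] < pct_out_max)
    )
    table = table[MARKER_COLUMNS + ["retained"]].sort_values(
        ["group", "p_adj", "feature"], ignore_index=True
    )
    log.info(
        "DEPA detection: %d tests, %d retained across %d groups",
        len(table),
        int(table["retained"].sum()),
        len(groups),
    )
    return table


def _metric_group_test(
    metric: MetricMatrix,
    labels: pd.Series,
    kind: str,
    groups_in_out: Sequence[tuple[str, str, np.ndarray, np.ndarray]],
    alpha: float,
    method: str,
    min_cells: int,
    directions: tuple[str, str],
):
    """Shared Wilcoxon machinery for PPUI / weighted-length tests."""
    values = metric.values
    rows = []
    untested = []
    for group, contrast, in_mask, out_mask in groups_in_out:
        for gi, gene in enumerate(metric.genes):
            x = values[gi, in_mask]
            y = values[gi, out_mask]
            x = x[~np.isnan(x)]
            y = y[~np.isnan(y)]
            if len(x) < min_cells or len(y) < min_cells:
                untested.append((gene, group))
                continue
            u, p = rank_sum_test(x, y)
            effect = float(np.mean(x) - np.mean(y))
            rows.append(
                dict(
                    feature=gene,
                    kind=kind,
                    group=group,
                    contrast=contrast,
                    statistic=u,
                    p_raw=p,
                    effect=effect,
                    pct_in=len(x) / max(int(in_mask.sum()), 1),
                    pct_out=len(y) / max(int(out_mask.sum()), 1),
                )
            )
    table = pd.DataFrame(rows)
    if untested:
        log.info("%s: %d (gene, group) pairs untested (insufficient defined cells)", kind, len(untested))
    if table.empty:
        table = pd.DataFrame(columns=MARKER_COLUMNS + ["significant"])
        table.attrs["untested"] = untested
        return table
    table["p_adj"] = _adjust(table["p_raw"].to_numpy(), method)
    up, down = directions
    table["direction"] = np.where(table["effect"] > 0, up, down)
    table["significant"] = table["p_adj"] < alpha
    table = table[MARKER_COLUMNS + ["significant"]].sort_values(
        ["group", "p_adj", "feature"], ignore_index=True
    )
    table.attrs["untested"] = untested
    return table


def find_apa_markers(
    metric: MetricMatrix,
    labels: pd.Series,
    contrast: str = "one_vs_rest",
    alpha: float = 0.05,
    method: str = "fdr_bh",
    min_cells: int = 10,
) -> pd.DataFrame:
    """Genes with differential proximal-site usage (PPUI) across groups.

    ``contrast`` is ``"one_vs_rest"`` (each group against all other
    cells) or ``"pairwise"`` (every ordered group pair).  Effect is the
    difference of group mean PPUI; direction ``up`` means a proximal
    shift (3'UTR shortening) in the target group.
    """
    if metric.kind != "ppui":
        raise ValueError("find_apa_markers expects a PPUI MetricMatrix")
    labels = _check_labels(labels, pd.Index(metric.cells))
    groups = sorted(labels.unique())
    combos = []
    if contrast == "one_vs_rest":
        for g in groups:
            mask = (labels == g).to_numpy()
            combos.append((g, "one_vs_rest", mask, ~mask))
    elif contrast == "pairwise":
        for g in groups:
            for h in groups:
                if g == h:
                    continue
                combos.append(
                    (g, f"pairwise({h})", (labels == g).to_numpy(), (labels == h).to_numpy())
                )
    else:
        raise ValueError(f"unknown contrast: {contrast}")
    return _metric_group_test(
        metric, labels, "APA_marker", combos, alpha, method, min_cells, ("up", "down")
    )


def find_switching_genes(
    metric: MetricMatrix,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    method: str = "fdr_bh",
    min_cells: int = 10,
) -> pd.DataFrame:
    """APA switching genes between two named groups, with direction.

    Tests each gene's weighted 3'UTR length between ``group_a`` and
    ``group_b``; direction is ``lengthening`` in ``group_a`` when its
    mean length exceeds ``group_b``'s, else ``shortening``.
    """
    if metric.kind != "weighted_length":
        raise ValueError("find_switching_genes expects a weighted_length MetricMatrix")
    labels = _check_labels(labels, pd.Index(metric.cells))
    for g in (group_a, group_b):
        if g not in set(labels):
            raise ValueError(f"group {g!r} absent from labels")
    mask_a = (labels == group_a).to_numpy()
    mask_b = (labels == group_b).to_numpy()
    combos = [(group_a, f"pairwise({group_b})", mask_a, mask_b)]
    return _metric_group_test(
        metric,
        labels,
        "switching_gene",
        combos,
        alpha,
        method,
        min_cells,
        ("lengthening", "shortening"),
    )


def nonredundant_apa_genes(
    depas: pd.DataFrame,
    apa_markers: pd.DataFrame,
    site_genes: Mapping[str, str] | pd.Series,
) -> dict[str, set[str]]:
    """Per-group union of DEPA-owning genes and APA-marker genes.

    ``site_genes`` maps site id → gene id for resolving DEPA sites.
    Only retained DEPAs / significant APA markers contribute.
    """
    site_genes = pd.Series(site_genes)
    out: dict[str, set[str]] = {}
    if not depas.empty:
        kept = depas[depas.get("retained", True)]
        for group, sub in kept.groupby("group"):
            genes = site_genes.reindex(sub["feature"]).dropna()
            out.setdefault(str(group), set()).update(genes)
    if not apa_markers.empty:
        kept = apa_markers[apa_markers.get("significant", True)]
        for group, sub in kept.groupby("group"):
            out.setdefault(str(group), set()).update(sub["feature"])
    return out
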