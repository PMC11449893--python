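"""Marker detection: rank-sum correctness against independent oracles,
the DEPA retention rules, direction semantics, and invariances."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, rankdata

import scapa_atlas as sa
from scapa_atlas._stats import rank_sum_test
from scapa_atlas.containers import MetricMatrix


def _enumeration_p(x, y):
    """Test-local exact two-sided rank-sum p, written independently."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, N = len(x), len(pooled)
    e_w = n * (N + 1) / 2.0
    obs = abs(ranks[:n].sum() - e_w)
    hits = sum(
        1
        for idx in combinations(range(N), n)
        if abs(sum(ranks[i] for i in idx) - e_w) >= obs - 1e-9
    )
    return hits / comb(N, n)


@pytest.mark.parametrize("n,m", [(n, m) for n in range(2, 9) for m in range(2, 9)])
def test_small_sample_exact_p_matches_scipy_without_ties(n, m):
    rng = np.random.default_rng(1000 * n + m)
    x = rng.permutation(np.arange(n + m, dtype=float))[:n]
    y = np.setdiff1d(np.arange(n + m, dtype=float), x)
    _, p = rank_sum_test(x, y)
    p_scipy = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    assert p == pytest.approx(p_scipy, abs=1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_small_sample_exact_p_matches_enumeration_with_ties(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 3, size=rng.integers(2, 7)).astype(float)
    y = rng.integers(0, 3, size=rng.integers(2, 7)).astype(float)
    _, p = rank_sum_test(x, y)
    assert p == pytest.approx(_enumeration_p(x, y), abs=1e-12)


def test_large_sample_uses_corrected_normal_approximation():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 50)
    y = rng.normal(0.8, 1, 60)
    u, p = rank_sum_test(x, y)
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert (u, p) == (pytest.approx(res.statistic), pytest.approx(res.pvalue))


def test_degenerate_constant_data_p_is_one():
    assert rank_sum_test(np.ones(20), np.ones(30))[1] == 1.0


def _site_matrix(counts, groups):
    counts = np.asarray(counts)
    sites = pd.DataFrame(
        {"chrom": "c1", "start": 0, "end": 10, "strand": "+"},
        index=pd.Index([f"s{i}" for i in range(counts.shape[0])], name="site_id"),
    )
    cells = pd.DataFrame(
        {"batch": "x", "group": groups},
        index=pd.Index([f"c{i}" for i in range(counts.shape[1])], name="cell_id"),
    )
    return sa.SiteMatrix(counts=sp.csr_matrix(counts), sites=sites, cells=cells)


def test_perfectly_separating_site_is_a_depa():
    groups = ["A"] * 10 + ["B"] * 10
    counts = np.vstack(
        [
            [8] * 10 + [0] * 10,     # A-specific site
            [3] * 20,                # flat site: not retained
        ]
    )
    m = _site_matrix(counts, groups)
    table = sa.find_depas(m, m.cells["group"], min_cells=3)
    a = table[(table.feature == "s0") & (table.group == "A")].iloc[0]
    assert a.retained and a.pct_in == 1.0 and a.pct_out == 0.0 and a.direction == "up"
    assert not table[(table.feature == "s1")]["retained"].any()


def test_bonferroni_uses_number_of_tests_performed():
    rng = np.random.default_rng(4)
    counts = rng.poisson(3, size=(6, 40))
    counts[0, :20] += 12
    m = _site_matrix(counts, ["A"] * 20 + ["B"] * 20)
    table = sa.find_depas(m, m.cells["group"], min_cells=3)
    m_tests = len(table)
    expect = np.minimum(1.0, table["p_raw"] * m_tests)
    np.testing.assert_allclose(table["p_adj"], expect)


def test_cell_order_permutation_changes_nothing():
    rng = np.random.default_rng(5)
    counts = rng.poisson(2, size=(5, 60))
    counts[1, :30] += 6
    groups = ["A"] * 30 + ["B"] * 30
    m = _site_matrix(counts, groups)
    base = sa.find_depas(m, m.cells["group"], min_cells=3)
    perm = rng.permutation(60)
    m2 = sa.SiteMatrix(
        counts=sp.csr_matrix(counts[:, perm]),
        sites=m.sites,
        cells=m.cells.iloc[perm],
    )
    other = sa.find_depas(m2, m2.cells["group"], min_cells=3)
    pd.testing.assert_frame_equal(
        base.sort_values(["feature", "group"], ignore_index=True),
        other.sort_values(["feature", "group"], ignore_index=True),
    )


def _metric(values, kind="ppui"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return MetricMatrix(
        values=values,
        genes=pd.Index([f"g{i}" for i in range(values.shape[0])]),
        cells=pd.Index([f"c{i}" for i in range(values.shape[1])]),
        kind=kind,
    )


def _labels(groups):
    return pd.Series(groups, index=[f"c{i}" for i in range(len(groups))])


def test_constant_metric_gene_is_not_significant():
    mm = _metric([[0.5] * 40])
    table = sa.find_apa_markers(mm, _labels(["A"] * 20 + ["B"] * 20), min_cells=5)
    assert table["p_raw"].iloc[0] == 1.0
    assert not table["significant"].any()


def test_insufficient_defined_cells_reported_untested():
    values = np.full((1, 40), np.nan)
    values[0, :4] = 0.5
    mm = _metric(values)
    table = sa.find_apa_markers(mm, _labels(["A"] * 20 + ["B"] * 20), min_cells=10)
    assert table.empty
    assert ("g0", "A") in table.attrs["untested"]


def test_switching_swapped_groups_flips_direction_only():
    rng = np.random.default_rng(6)
    vals = np.concatenate([rng.normal(300, 20, 25), rng.normal(180, 20, 25)])
    mm = _metric([vals], kind="weighted_length")
    labels = _labels(["A"] * 25 + ["B"] * 25)
    ab = sa.find_switching_genes(mm, labels, "A", "B")
    ba = sa.find_switching_genes(mm, labels, "B", "A")
    assert ab["p_raw"].iloc[0] == pytest.approx(ba["p_raw"].iloc[0])
    assert ab["direction"].iloc[0] == "lengthening"
    assert ba["direction"].iloc[0] == "shortening"
    assert ab["effect"].iloc[0] == pytest.approx(-ba["effect"].iloc[0])


def test_two_site_genes_ppui_up_means_shortening(refine_run):
    """Affine link between the metrics: a proximal shift (PPUI up) in a
    group is exactly a 3'UTR shortening call for 2-site genes."""
    truth = refine_run.truth
    labels = refine_run.labels
    two_site = {
        g
        for g, n in truth.sites.groupby("gene_id").size().items()
        if n == 2 and g in set(truth.shift_genes.index)
    }
    checked = 0
    pp = sa.find_apa_markers(refine_run.ppui, labels, contrast="pairwise", min_cells=10)
    for g in sorted(two_site):
        target = truth.shift_genes.loc[g, "target_type"]
        other = next(t for t in truth.cell_types if t != target)
        rec_pp = pp[(pp.feature == g) & (pp.group == target) & (pp.contrast == f"pairwise({other})")]
        sw = sa.find_switching_genes(refine_run.lengths, labels, target, other)
        rec_sw = sw[sw.feature == g]
        if rec_pp.empty or rec_sw.empty:
            continue
        up = rec_pp["direction"].iloc[0] == "up"
        shortening = rec_sw["direction"].iloc[0] == "shortening"
        assert up == shortening
        checked += 1
        if checked >= 3:
            break
    assert checked >= 1


def test_nonredundant_union_deduplicates():
    depas = pd.DataFrame(
        {
            "feature": ["s1", "s2", "s3"],
            "group": ["A", "A", "B"],
            "retained": [True, True, True],
        }
    )
    apa = pd.DataFrame(
        {
            "feature": ["gX", "gY"],
            "group": ["A", "B"],
            "significant": [True, True],
        }
    )
    site_genes = pd.Series({"s1": "gX", "s2": "gZ", "s3": "gW"})
    sets = sa.nonredundant_apa_genes(depas, apa, site_genes)
    assert sets["A"] == {"gX", "gZ"}  # gX counted once
    assert sets["B"] == {"gW", "gY"}
    assert len(sets["A"]) >= 2
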