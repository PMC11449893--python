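"""3'UTR assignment: coordinate conventions, the 1000-nt extension rule,
strand handling, and the nucleotide-composition profile."""

import textwrap

import numpy as np
import pandas as pd
import pytest

import scapa_atlas as sa
from scapa_atlas import annotate as ann


def _gtf(lines: str) -> str:
    return textwrap.dedent(lines).strip() + "\n"


@pytest.fixture(scope="module")
def toy_model(tmp_path_factory):
    """Three genes: '+' with UTR, '−' with UTR, '+' without UTR record."""
    gtf = _gtf(
        """
        chr1\tt\tgene\t501\t1200\t.\t+\t.\tgene_id "gp"; transcript_id "gp.1"; gene_biotype "protein_coding";
        chr1\tt\ttranscript\t501\t1200\t.\t+\t.\tgene_id "gp"; transcript_id "gp.1";
        chr1\tt\tCDS\t501\t1000\t.\t+\t.\tgene_id "gp"; transcript_id "gp.1";
        chr1\tt\tstop_codon\t998\t1000\t.\t+\t.\tgene_id "gp"; transcript_id "gp.1";
        chr1\tt\tthree_prime_utr\t1001\t1200\t.\t+\t.\tgene_id "gp"; transcript_id "gp.1";
        chr2\tt\tgene\t5001\t5800\t.\t-\t.\tgene_id "gm"; transcript_id "gm.1"; gene_biotype "protein_coding";
        chr2\tt\ttranscript\t5001\t5800\t.\t-\t.\tgene_id "gm"; transcript_id "gm.1";
        chr2\tt\tCDS\t5301\t5800\t.\t-\t.\tgene_id "gm"; transcript_id "gm.1";
        chr2\tt\tstop_codon\t5301\t5303\t.\t-\t.\tgene_id "gm"; transcript_id "gm.1";
        chr2\tt\tthree_prime_utr\t5001\t5300\t.\t-\t.\tgene_id "gm"; transcript_id "gm.1";
        chr3\tt\tgene\t301\t800\t.\t+\t.\tgene_id "gn"; transcript_id "gn.1"; gene_biotype "protein_coding";
        chr3\tt\ttranscript\t301\t800\t.\t+\t.\tgene_id "gn"; transcript_id "gn.1";
        chr3\tt\tCDS\t301\t800\t.\t+\t.\tgene_id "gn"; transcript_id "gn.1";
        chr3\tt\tstop_codon\t798\t800\t.\t+\t.\tgene_id "gn"; transcript_id "gn.1";
        """
    )
    path = tmp_path_factory.mktemp("toy") / "toy.gtf"
    path.write_text(gtf)
    return sa.load_gene_model(str(path))


def test_extension_is_strand_aware(toy_model):
    gp = toy_model.loc["gp"]
    assert (gp.utr_start, gp.utr_end) == (1000, 1200)
    assert (gp.ext_start, gp.ext_end) == (1000, 2200)
    gm = toy_model.loc["gm"]
    assert (gm.utr_start, gm.utr_end) == (5000, 5300)
    assert (gm.ext_start, gm.ext_end) == (4000, 5300)


def test_missing_utr_anchored_at_stop_codon(toy_model):
    gn = toy_model.loc["gn"]
    assert gn.utr_start == gn.utr_end == 800
    assert (gn.ext_start, gn.ext_end) == (800, 1800)
    assert gn.stop_pos == 800


def _peaks(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand"],
        index=[f"p{i}" for i in range(len(rows))],
    )


def test_containment_and_1000nt_boundary(toy_model):
    # '+' gene gp: UTR [1000,1200), extension to 2200.  Representative
    # coordinate of a '+' peak is end-1.
    peaks = _peaks(
        [
            ("chr1", 1080, 1101, "+"),   # coord 1100: annotated 3'UTR
            ("chr1", 2178, 2199, "+"),   # coord 2198: 999 nt past UTR end
            ("chr1", 2250, 2271, "+"),   # coord 2270: beyond extension
            ("chr1", 1080, 1101, "-"),   # wrong strand
            ("chr9", 1080, 1101, "+"),   # unknown chromosome
        ]
    )
    out = sa.annotate_sites(peaks, toy_model)
    assert list(out["region"]) == ["3UTR", "extended_3UTR", "other", "other", "other"]
    assert out.loc["p0", "gene_id"] == "gp"
    assert out.loc["p0", "L"] == 1100 - 1000
    assert out.loc["p1", "L"] == 2198 - 1000


def test_minus_strand_distance(toy_model):
    # gm: stop at 5299; '-' peak coordinate is its start.
    peaks = _peaks([("chr2", 5100, 5121, "-")])
    out = sa.annotate_sites(peaks, toy_model)
    assert out.loc["p0", "region"] == "3UTR"
    assert out.loc["p0", "L"] == 5299 - 5100


def test_malformed_interval_raises(toy_model):
    with pytest.raises(ValueError, match="malformed"):
        sa.annotate_sites(_peaks([("chr1", 1100, 1100, "+")]), toy_model)


def test_annotation_is_order_independent(toy_model):
    peaks = _peaks(
        [
            ("chr1", 1080, 1101, "+"),
            ("chr1", 1500, 1521, "+"),
            ("chr2", 5100, 5121, "-"),
        ]
    )
    a = sa.annotate_sites(peaks, toy_model)
    b = sa.annotate_sites(peaks.iloc[::-1], toy_model).loc[a.index]
    pd.testing.assert_frame_equal(a, b)


def test_strand_antisymmetry(toy_model):
    """Mirroring all coordinates and flipping strands preserves regions/L."""
    M = 100_000
    mirrored = toy_model.copy()
    mirrored["strand"] = np.where(toy_model["strand"] == "+", "-", "+")
    mirrored["utr_start"] = M - toy_model["utr_end"]
    mirrored["utr_end"] = M - toy_model["utr_start"]
    mirrored["ext_start"] = M - toy_model["ext_end"]
    mirrored["ext_end"] = M - toy_model["ext_start"]
    mirrored["stop_pos"] = M - 1 - toy_model["stop_pos"]
    peaks = _peaks(
        [
            ("chr1", 1080, 1101, "+"),
            ("chr1", 2178, 2199, "+"),
            ("chr2", 5100, 5121, "-"),
        ]
    )
    flipped = peaks.copy()
    flipped["start"] = M - peaks["end"]
    flipped["end"] = M - peaks["start"]
    flipped["strand"] = np.where(peaks["strand"] == "+", "-", "+")
    a = sa.annotate_sites(peaks, toy_model)
    b = sa.annotate_sites(flipped, mirrored)
    assert list(a["region"]) == list(b["region"])
    assert list(a["L"].fillna(-1)) == list(b["L"].fillna(-1))


def test_filter_retains_only_utr_sites_and_conserves_counts(small_run):
    """Synthetic construction: the planted 'other' fraction is dropped
    exactly, everything else survives with counts untouched."""
    truth = small_run.truth
    batch = small_run.batches["batch0"]
    annotated = sa.annotate_sites(batch.sites, small_run.model)
    filtered = sa.filter_3utr_matrix(batch, annotated)
    n_other = (truth.sites["region_true"] == "other").sum()
    assert batch.n_sites - filtered.n_sites == n_other
    keep_mask = annotated["region"] != "other"
    expected_total = int(batch.counts[keep_mask.to_numpy()].sum())
    assert filtered.total_counts() == expected_total
    # true region labels agree with annotation after the batch prefix is
    # stripped (construction oracle)
    true_regions = truth.sites["region_true"]
    stripped = annotated.index.str.split("_", n=1).str[1]
    assert (annotated["region"].to_numpy() == true_regions[stripped].to_numpy()).all()


def test_nucleotide_profile_recovers_planted_hexamer(small_run, tmp_path):
    fasta = tmp_path / "genome.fa"
    sa.generate_genome_fasta(small_run.truth, str(fasta), signal_fraction=1.0)
    sites = small_run.truth.sites
    prof = sa.nucleotide_profile(sites, str(fasta), flank=40)
    sums = prof.sum(axis=1)
    assert np.allclose(sums, 1.0)
    # AATAAA planted at transcript positions -25..-20 of every site
    for pos, base in zip(range(-25, -19), "AAUAAA"):
        assert prof.loc[pos, base] == pytest.approx(1.0)
    # background positions are ~uniform
    assert prof.loc[10].max() < 0.5


def test_nucleotide_profile_one_hot_for_single_site(tmp_path):
    fasta = tmp_path / "tiny.fa"
    fasta.write_text(">c\nAACGTAC\n")
    sites = pd.DataFrame(
        {"chrom": ["c"], "start": [0], "end": [4], "strand": ["+"], "coord": [3]},
        index=["s1"],
    )
    prof = sa.nucleotide_profile(sites, str(fasta), flank=2)
    # sequence around coord 3 ('G') is ACGTA -> positions -2..2
    expect = {-2: "A", -1: "C", 0: "G", 1: "U", 2: "A"}
    for pos, base in expect.items():
        assert prof.loc[pos, base] == 1.0
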