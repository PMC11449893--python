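"""Assignment of poly(A)-site peaks to gene 3'UTR regions.

A 3'-tag peak is kept only if its representative cleavage position falls
in a protein-coding gene's annotated 3'UTR or in the 3'UTR *extension*:
the annotated 3'UTR grown 1000 nt downstream (in the direction of
transcription) to capture cleavage sites beyond the annotated 3' end.
Everything else is labelled ``other`` and discarded from APA analysis.

Coordinates are 0-based half-open internally; GTF input (1-based,
closed) is converted on read.  The representative coordinate of a peak
is its strand-aware *distal* end — the last covered base furthest
downstream: ``end - 1`` on '+', ``start`` on '−'.
"""

from __future__ import annotations

import logging
from typing import Iterable

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

REGION_3UTR = "3UTR"
REGION_EXT = "extended_3UTR"
REGION_OTHER = "other"

#: Downstream growth of the annotated 3'UTR, in nt.
DEFAULT_EXTENSION = 1000


class GeneModelError(ValueError):
    """Unusable gene-annotation input (missing strand, no 3' anchor...)."""


def representative_coord(start, end, strand):
    """Strand-aware distal end of a half-open peak interval.

    The most downstream covered base: ``end - 1`` on '+', ``start`` on '−'.
    Accepts scalars or aligned arrays.
    """
    start = np.asarray(start)
    end = np.asarray(end)
    coord = np.where(np.asarray(strand) == "+", end - 1, start)
    if coord.ndim == 0:
        return int(coord)
    return coord.astype(int)


def load_gene_model(
    gtf_path: str, extension: int = DEFAULT_EXTENSION, protein_coding_only: bool = True
) -> pd.DataFrame:
    """Read a GTF/GFF3 gene model into a per-gene 3'UTR table.

    Returns a DataFrame indexed by gene id with columns ``chrom, strand,
    stop_pos, utr_start, utr_end, ext_start, ext_end, biotype``.  The
    3'UTR interval is the union span of the gene's ``three_prime_utr``
    records; genes without one get a zero-length 3'UTR anchored at the
    stop codon (derivable from a ``stop_codon`` or ``CDS`` record), so
    the downstream extension window still applies.  ``stop_pos`` is the
    0-based position from which site distances L are measured: the first
    3'UTR base ('+') or the last one ('−').
    """
    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records = []
    bad: list[str] = []
    for gene in db.features_of_type("gene"):
        gid = gene.id
        if gene.strand not in ("+", "-"):
            bad.append(gid)
            continue
        biotype = (
            gene.attributes.get("gene_biotype", gene.attributes.get("gene_type", ["protein_coding"]))
        )[0]
        if protein_coding_only and biotype != "protein_coding":
            continue
        utrs = [
            f
            for f in db.children(gene, featuretype=("three_prime_utr", "three_prime_UTR"))
        ]
        if utrs:
            # gffutils keeps GTF 1-based closed coords; convert.
            utr_start = min(f.start for f in utrs) - 1
            utr_end = max(f.end for f in utrs)
        else:
            stops = list(db.children(gene, featuretype="stop_codon"))
            if not stops:
                stops = list(db.children(gene, featuretype="CDS"))
            if not stops:
                bad.append(gid)
                continue
            if gene.strand == "+":
                anchor = max(f.end for f in stops)  # 1-based end == 0-based past-end
                utr_start = utr_end = anchor
            else:
                anchor = min(f.start for f in stops) - 1
                utr_start = utr_end = anchor
        if gene.strand == "+":
            ext_start, ext_end = utr_start, utr_end + extension
            stop_pos = utr_start
        else:
            ext_start, ext_end = max(0, utr_start - extension), utr_end
            stop_pos = utr_end - 1
        records.append(
            dict(
                gene_id=gid,
                chrom=gene.seqid,
                strand=gene.strand,
                stop_pos=stop_pos,
                utr_start=utr_start,
                utr_end=utr_end,
                ext_start=ext_start,
                ext_end=ext_end,
                biotype=biotype,
            )
        )
    if bad:
        raise GeneModelError(
            f"{len(bad)} gene records lack a strand or a 3' anchor "
            f"(3'UTR/stop_codon/CDS): {bad[:10]}"
        )
    if not records:
        raise GeneModelError(f"no usable gene records in {gtf_path}")
    model = pd.DataFrame.from_records(records).set_index("gene_id")
    return model


def _region_trees(model: pd.DataFrame):
    """Interval trees of (gene, region kind) per (chrom, strand)."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for gid, g in model.iterrows():
        key = (g.chrom, g.strand)
        tree = trees.setdefault(key, IntervalTree())
        if g.utr_end > g.utr_start:
            tree.addi(g.utr_start, g.utr_end, (gid, REGION_3UTR))
        if g.ext_end > g.ext_start:
            tree.addi(g.ext_start, g.ext_end, (gid, REGION_EXT))
    return trees


def annotate_sites(peaks: pd.DataFrame, model: pd.DataFrame) -> pd.DataFrame:
    """Assign peaks to 3'UTR / extended-3'UTR regions of a gene model.

    ``peaks`` needs ``chrom, start, end, strand`` columns (0-based
    half-open).  The test is point containment of the representative
    coordinate, on the same strand.  Ambiguity between genes is resolved
    by preferring an annotated 3'UTR over an extension, then the nearest
    stop codon, then lexicographic gene id.  Returns a copy of ``peaks``
    with ``coord, gene_id, region, L`` columns added; unassigned peaks
    get region ``other`` and NaN gene/L.
    """
    bad = peaks.index[peaks["start"] >= peaks["end"]]
    if len(bad):
        raise ValueError(f"malformed peak intervals (start >= end): {list(bad[:5])}")
    trees = _region_trees(model)
    stop_pos = model["stop_pos"]
    known_chroms = set(model["chrom"])

    out = peaks.copy()
    coords = representative_coord(
        peaks["start"].to_numpy(), peaks["end"].to_numpy(), peaks["strand"].to_numpy()
    )
    genes: list = []
    regions: list = []
    dists: list = []
    missing_chroms: set[str] = set()
    rank = {REGION_3UTR: 0, REGION_EXT: 1}
    for (chrom, strand, coord) in zip(peaks["chrom"], peaks["strand"], coords):
        if chrom not in known_chroms:
            missing_chroms.add(chrom)
        tree = trees.get((chrom, strand))
        hits = tree[coord] if tree is not None else set()
        if not hits:
            genes.append(np.nan)
            regions.append(REGION_OTHER)
            dists.append(np.nan)
            continue
        best = min(
            hits,
            key=lambda iv: (
                rank[iv.data[1]],
                abs(coord - stop_pos[iv.data[0]]),
                iv.data[0],
            ),
        )
        gid, region = best.data
        L = coord - stop_pos[gid] if strand == "+" else stop_pos[gid] - coord
        genes.append(gid)
        regions.append(region)
        dists.append(int(L))
    if missing_chroms:
        log.warning(
            "peaks on %d chromosome(s) absent from the gene model labelled 'other': %s",
            len(missing_chroms),
            sorted(missing_chroms)[:5],
        )
    out["coord"] = coords
    out["gene_id"] = genes
    out["region"] = regions
    out["L"] = dists
    return out


def filter_3utr_matrix(matrix, annotated_sites: pd.DataFrame):
    """Keep only sites assigned to a (possibly extended) 3'UTR.

    ``annotated_sites`` must cover every site of ``matrix``.  Counts are
    untouched; the cell set is unchanged.  Raises if nothing survives.
    """
    regions = annotated_sites["region"].reindex(matrix.site_ids)
    if regions.isna().any():
        missing = list(matrix.site_ids[regions.isna()][:5])
        raise ValueError(f"sites missing from annotation: {missing}")
    keep = matrix.site_ids[regions.isin([REGION_3UTR, REGION_EXT])]
    if len(keep) == 0:
        raise ValueError("no sites in 3'UTR or extended 3'UTR regions")
    log.info("3'UTR filter: %d/%d sites retained", len(keep), matrix.n_sites)
    filtered = matrix.subset_sites(keep)
    return filtered.with_sites(annotated_sites.loc[keep])


def nucleotide_profile(
    sites: pd.DataFrame, fasta_path: str, flank: int = 100
) -> pd.DataFrame:
    """Per-position base composition around cleavage sites.

    For each site the strand-oriented sequence from −``flank`` to
    +``flank`` around the representative coordinate is taken (position 0
    is the cleavage site; '−'-strand sequences are reverse-complemented)
    and per-position A/C/G/U frequencies are computed over non-N bases.
    Sites too close to a contig edge are skipped; the skip count is in
    ``df.attrs["n_skipped"]``.
    """
    from pyfaidx import Fasta

    comp = str.maketrans("ACGTN", "TGCAN")
    genome = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    width = 2 * flank + 1
    tallies = {b: np.zeros(width, dtype=np.int64) for b in "ACGT"}
    n_used = 0
    n_skipped = 0
    for _, s in sites.iterrows():
        coord = (
            s["coord"]
            if "coord" in s and not pd.isna(s["coord"])
            else representative_coord(s["start"], s["end"], s["strand"])
        )
        coord = int(coord)
        if s["chrom"] not in genome:
            n_skipped += 1
            continue
        contig = genome[s["chrom"]]
        lo, hi = coord - flank, coord + flank + 1
        if lo < 0 or hi > len(contig):
            n_skipped += 1
            continue
        seq = contig[lo:hi]
        if s["strand"] == "-":
            seq = seq.translate(comp)[::-1]
        for pos, base in enumerate(seq):
            if base in tallies:
                tallies[base][pos] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no site had a full flanking window in the genome")
    counts = pd.DataFrame(tallies, index=np.arange(-flank, flank + 1))
    freqs = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0)
    freqs = freqs.rename(columns={"T": "U"})[["A", "C", "G", "U"]]
    freqs.index.name = "position"
    freqs.attrs["n_sites"] = n_used
    freqs.attrs["n_skipped"] = n_skipped
    if n_skipped:
        log.warning("nucleotide_profile: %d sites skipped near contig edges", n_skipped)
    return freqs
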