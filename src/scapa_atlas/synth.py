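"""Multi-batch synthetic 3'-tag poly(A)-site data with planted truth.

The generator emulates the structure of a multi-study single-cell
poly(A)-site compendium: discrete cell types with lowly expressed
marker genes, genes with two or three 3'UTR poly(A) sites whose
proximal-usage fraction differs by cell type (APA shift genes),
per-batch sequencing-depth differences, and per-batch jitter of peak
interval boundaries, so the same biological site has non-identical but
intersecting peak intervals across batches.

Count model: a cell's total count for a gene is negative binomial with
mean = base expression × marker fold (if the gene marks the cell's
type) × batch depth factor, and dispersion θ (variance μ + μ²/θ).  The
gene total is then allocated to the gene's sites by a multinomial whose
proximal probability is the planted π(type, gene), the remaining mass
split uniformly over distal sites.  Because multinomial proportions are
conditionally unbiased, the planted π is also the exact expected PPUI,
which makes closed-form oracles possible (:func:`expected_metrics`).

All randomness flows from one root seed through named substreams, so a
fixed seed reproduces every file byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import SiteMatrix

log = logging.getLogger(__name__)


class SynthesisError(ValueError):
    """Infeasible generator configuration (placement, jitter, fractions)."""


@dataclass
class SynthConfig:
    """Study conditions of a synthetic compendium.

    Defaults describe a desk-scale analogue of a multi-batch root
    atlas: 4 cell types × 200 cells per type per batch × 3 batches with
    uneven depth, 10% marker genes at fold 4 (lowly expressed
    off-target, as cell-type-restricted transcripts are), 10% APA shift
    genes with proximal fraction 0.8 against a 0.3 background, and ±5 nt
    peak-boundary jitter per batch.
    """

    n_genes: int = 200
    #: probability of a gene carrying 1, 2 or 3 3'UTR sites
    sites_per_gene: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.3, 2: 0.5, 3: 0.2}
    )
    n_cell_types: int = 4
    cells_per_type_per_batch: int = 200
    n_batches: int = 3
    depth_factor_per_batch: Sequence[float] = (1.0, 1.5, 0.7)
    marker_gene_fraction: float = 0.1
    marker_fold_change: float = 4.0
    #: off-target gene-level mean count of marker genes
    marker_base_mean: float = 0.3
    shift_gene_fraction: float = 0.1
    proximal_fraction_base: float = 0.3
    proximal_fraction_shifted: float = 0.8
    #: per-gene mean count of non-marker genes, drawn uniformly
    base_expression_range: tuple[float, float] = (1.0, 4.0)
    nb_dispersion: float = 10.0
    interval_jitter_max: int = 5
    peak_half_width: int = 10
    utr_length_range: tuple[int, int] = (50, 500)
    #: fraction of genes given one extra site downstream of the
    #: annotated 3'UTR end but within the 1000-nt extension window
    extension_site_fraction: float = 0.0
    #: fraction of genes given one extra site beyond the 1000-nt window
    beyond_extension_fraction: float = 0.0
    n_chromosomes: int = 2
    chromosome_length: int | None = None
    seed: int = 0

    #: spacing layout constants (nt)
    _cds_length: int = 300
    _chrom_margin: int = 3000
    _gene_gap: int = 500

    @property
    def min_site_gap(self) -> int:
        """Smallest distance between true site coordinates of one gene.

        Chosen so that even maximally jittered peak intervals of
        distinct sites never intersect.
        """
        return 2 * (self.peak_half_width + self.interval_jitter_max) + 2

    def validate(self) -> None:
        fracs = {
            "marker_gene_fraction": self.marker_gene_fraction,
            "shift_gene_fraction": self.shift_gene_fraction,
            "proximal_fraction_base": self.proximal_fraction_base,
            "proximal_fraction_shifted": self.proximal_fraction_shifted,
            "extension_site_fraction": self.extension_site_fraction,
            "beyond_extension_fraction": self.beyond_extension_fraction,
        }
        for name, value in fracs.items():
            if not 0 <= value <= 1:
                raise SynthesisError(f"{name}={value} outside [0, 1]")
        if self.n_genes <= 0 or self.n_cell_types <= 0 or self.n_batches <= 0:
            raise SynthesisError("n_genes, n_cell_types, n_batches must be positive")
        if len(self.depth_factor_per_batch) != self.n_batches:
            raise SynthesisError(
                "depth_factor_per_batch must have one factor per batch"
            )
        if any(d <= 0 for d in self.depth_factor_per_batch):
            raise SynthesisError("depth factors must be positive")
        if self.marker_fold_change <= 1:
            raise SynthesisError("marker_fold_change must exceed 1")
        lo, hi = self.utr_length_range
        if lo >= hi:
            raise SynthesisError("utr_length_range low must be < high")
        probs = np.array([self.sites_per_gene.get(k, 0.0) for k in (1, 2, 3)])
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise SynthesisError("sites_per_gene must be a distribution over {1,2,3}")
        max_sites = max(k for k, p in self.sites_per_gene.items() if p > 0)
        if (hi - lo) < (max_sites - 1) * self.min_site_gap:
            raise SynthesisError(
                f"utr_length_range {self.utr_length_range} cannot hold "
                f"{max_sites} sites at minimum gap {self.min_site_gap} "
                "(jitter would let distinct-site intervals intersect)"
            )
        if self.nb_dispersion <= 0:
            raise SynthesisError("nb_dispersion must be positive")


@dataclass
class GroundTruth:
    """Planted truth of a synthetic compendium.

    ``genes``: per gene chrom/strand/stop codon/annotated 3'UTR,
    base mean, marker target type.  ``sites``: true coordinates, stop
    distances L, true region labels.  ``cells``: batch and true type
    (filled by :func:`generate_batches`).  ``shift_genes``: planted APA
    shifts with direction.  ``shares``: site × type multinomial
    allocation probabilities.  ``depa_sites``: site id → target type.
    """

    genes: pd.DataFrame
    sites: pd.DataFrame
    cells: pd.DataFrame
    shift_genes: pd.DataFrame
    shares: pd.DataFrame
    depa_sites: pd.Series
    config: SynthConfig

    @property
    def cell_types(self) -> list[str]:
        return [f"type{t}" for t in range(self.config.n_cell_types)]


def _draw_site_distances(rng, k, config: SynthConfig) -> np.ndarray:
    lo, hi = config.utr_length_range
    grid = np.arange(lo, hi + 1, config.min_site_gap)
    return np.sort(rng.choice(grid, size=k, replace=False))


def generate_gene_model(config: SynthConfig):
    """Lay out genes, sites and planted effects; return (gtf text, truth).

    Genes go on both strands of ``n_chromosomes`` chromosomes without
    overlap; each has a 300-nt CDS ending in a stop codon and an
    annotated 3'UTR covering its in-UTR sites.  A configurable fraction
    of genes gets one extra site in the 1000-nt extension window, and a
    fraction one site beyond it (discarded by annotation, exercising
    the filter).  The returned truth has an empty cell table.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    types = [f"type{t}" for t in range(config.n_cell_types)]

    ks = rng.choice(
        [1, 2, 3],
        size=config.n_genes,
        p=[config.sites_per_gene.get(i, 0.0) for i in (1, 2, 3)],
    )
    n_ext = int(round(config.extension_site_fraction * config.n_genes))
    n_beyond = int(round(config.beyond_extension_fraction * config.n_genes))
    extra = rng.permutation(config.n_genes)
    ext_genes = set(extra[:n_ext])
    beyond_genes = set(extra[n_ext : n_ext + n_beyond])

    multi = [i for i in range(config.n_genes) if ks[i] >= 2]
    n_shift = int(round(config.shift_gene_fraction * config.n_genes))
    if n_shift > len(multi):
        raise SynthesisError(
            f"cannot plant {n_shift} shift genes: only {len(multi)} genes have >=2 sites"
        )
    shift_idx = list(rng.choice(multi, size=n_shift, replace=False))
    # Marker genes are multi-site, disjoint from shift genes, and get a
    # *uniform* site allocation: keeping every site's share equal makes the
    # fold change a clean per-site detection-fraction contrast, which is
    # what the DEPA retention rule (detected >20% in, <20% out) measures.
    remaining = [i for i in multi if i not in set(shift_idx)]
    n_marker = int(round(config.marker_gene_fraction * config.n_genes))
    if n_marker > len(remaining):
        raise SynthesisError(
            "marker and shift fractions exceed the number of multi-site genes"
        )
    marker_idx = list(rng.choice(remaining, size=n_marker, replace=False))

    gene_rows, site_rows, shift_rows = [], [], []
    cursors = {c: config._chrom_margin for c in range(config.n_chromosomes)}
    hw = config.peak_half_width
    ext_d_lo = config.min_site_gap + 20
    for gi in range(config.n_genes):
        gid = f"g{gi:04d}"
        chrom = f"chr{gi % config.n_chromosomes + 1}"
        strand = "+" if (gi // config.n_chromosomes) % 2 == 0 else "-"
        k = int(ks[gi])
        L = list(_draw_site_distances(rng, k, config))
        utr_len = int(L[-1] + rng.integers(30, 80))
        extra_L = []
        if gi in ext_genes:
            extra_L.append(utr_len + int(rng.integers(ext_d_lo, 950)))
        if gi in beyond_genes:
            extra_L.append(utr_len + 1000 + int(rng.integers(60, 900)))
        footprint = config._cds_length + utr_len + 2000 + config._gene_gap
        start = cursors[gi % config.n_chromosomes]
        cursors[gi % config.n_chromosomes] = start + footprint
        if config.chromosome_length is not None and start + footprint > config.chromosome_length:
            raise SynthesisError(
                f"gene {gid} does not fit on {chrom} "
                f"(length {config.chromosome_length}); too many/too dense genes"
            )
        if strand == "+":
            cds_start = start
            cds_end = start + config._cds_length
            utr_start, utr_end = cds_end, cds_end + utr_len
            stop_pos = utr_start
            gene_start, gene_end = cds_start, utr_end
        else:
            utr_start, utr_end = start + 2000, start + 2000 + utr_len
            cds_start, cds_end = utr_end, utr_end + config._cds_length
            stop_pos = utr_end - 1
            gene_start, gene_end = utr_start, cds_end
        marker_type = (
            types[marker_idx.index(gi) % config.n_cell_types]
            if gi in marker_idx
            else None
        )
        gene_rows.append(
            dict(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                gene_start=gene_start,
                gene_end=gene_end,
                cds_start=cds_start,
                cds_end=cds_end,
                utr_start=utr_start,
                utr_end=utr_end,
                stop_pos=stop_pos,
                marker_type=marker_type,
            )
        )
        all_L = L + extra_L
        for si, dist in enumerate(all_L):
            coord = stop_pos + dist if strand == "+" else stop_pos - dist
            if strand == "+":
                s, e = coord - 2 * hw, coord + 1
            else:
                s, e = coord, coord + 2 * hw + 1
            region = (
                "3UTR"
                if dist <= utr_len
                else ("extended_3UTR" if dist <= utr_len + 1000 else "other")
            )
            site_rows.append(
                dict(
                    site_id=f"{gid}_s{si}",
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    start=s,
                    end=e,
                    coord=coord,
                    L=dist,
                    region_true=region,
                )
            )
        if gi in shift_idx:
            direction = "shortening" if shift_idx.index(gi) % 2 == 0 else "lengthening"
            target = types[shift_idx.index(gi) % config.n_cell_types]
            shift_rows.append(dict(gene_id=gid, target_type=target, direction=direction))

    genes = pd.DataFrame(gene_rows).set_index("gene_id")
    sites = pd.DataFrame(site_rows).set_index("site_id")
    shift_genes = pd.DataFrame(
        shift_rows, columns=["gene_id", "target_type", "direction"]
    ).set_index("gene_id")

    # Base expression: marker genes are lowly expressed off-target so the
    # fold change is a detection-fraction contrast; other genes are broadly
    # expressed.
    base = rng.uniform(*config.base_expression_range, size=config.n_genes)
    base[[genes.index.get_loc(g) for g in genes.index[genes["marker_type"].notna()]]] = (
        config.marker_base_mean
    )
    genes["base_mean"] = base

    shares = _allocation_shares(genes, sites, shift_genes, types, config)
    depa = sites.loc[
        sites["gene_id"].isin(genes.index[genes["marker_type"].notna()])
    ]["gene_id"].map(genes["marker_type"])
    depa.name = "target_type"

    truth = GroundTruth(
        genes=genes,
        sites=sites,
        cells=pd.DataFrame(columns=["batch", "cell_type"]),
        shift_genes=shift_genes,
        shares=shares,
        depa_sites=depa,
        config=config,
    )
    return _to_gtf(genes), truth


def _allocation_shares(genes, sites, shift_genes, types, config) -> pd.DataFrame:
    """Site × type multinomial probabilities implementing planted π."""
    rows = []
    for gid, gsites in sites.groupby("gene_id", sort=True):
        gsites = gsites.sort_values(["L", "site_id"] if "site_id" in gsites else "L")
        k = len(gsites)
        is_marker = genes.loc[gid, "marker_type"] is not None and not pd.isna(
            genes.loc[gid, "marker_type"]
        )
        for t in types:
            if k == 1:
                pi = 1.0
            elif is_marker:
                pi = 1.0 / k
            elif gid in shift_genes.index:
                target = shift_genes.loc[gid, "target_type"]
                direction = shift_genes.loc[gid, "direction"]
                hi, lo = config.proximal_fraction_shifted, config.proximal_fraction_base
                if direction == "shortening":
                    pi = hi if t == target else lo
                else:
                    pi = lo if t == target else hi
            else:
                pi = config.proximal_fraction_base
            w = np.full(k, (1 - pi) / (k - 1) if k > 1 else 0.0)
            w[0] = pi
            for sid, share in zip(gsites.index, w):
                rows.append(dict(site_id=sid, cell_type=t, share=share))
    shares = pd.DataFrame(rows).pivot(index="site_id", columns="cell_type", values="share")
    return shares.loc[sites.index]


def _to_gtf(genes: pd.DataFrame) -> str:
    """Render the gene table as GTF (1-based, closed intervals)."""
    lines = ["##gff-version 2", "#!synthetic gene model"]
    for gid, g in genes.iterrows():
        attrs = f'gene_id "{gid}"; transcript_id "{gid}.1"; gene_biotype "protein_coding";'
        feats = [
            ("gene", g.gene_start, g.gene_end),
            ("transcript", g.gene_start, g.gene_end),
            ("exon", g.gene_start, g.gene_end),
            ("CDS", g.cds_start, g.cds_end),
        ]
        if g.strand == "+":
            feats.append(("stop_codon", g.cds_end - 3, g.cds_end))
        else:
            feats.append(("stop_codon", g.cds_start, g.cds_start + 3))
        if g.utr_end > g.utr_start:
            feats.append(("three_prime_utr", g.utr_start, g.utr_end))
        for ftype, s0, e0 in feats:
            lines.append(
                "\t".join(
                    [
                        g.chrom,
                        "synth",
                        ftype,
                        str(s0 + 1),
                        str(e0),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def generate_batches(truth: GroundTruth, config: SynthConfig | None = None):
    """Simulate per-batch site × cell count matrices; fills ``truth.cells``.

    Returns a dict batch id → :class:`SiteMatrix`.  Batch peak intervals
    are the true intervals expanded outward by batch-specific uniform
    jitter in [0, interval_jitter_max] per boundary (so intervals of one
    true site always intersect across batches, while distinct sites of a
    gene — spaced at least ``min_site_gap`` apart — never do).
    """
    config = config or truth.config
    config.validate()
    types = truth.cell_types
    genes = truth.genes
    sites = truth.sites
    shares = truth.shares
    theta = config.nb_dispersion

    # Per-gene grouped site positions, ordered proximal -> distal.
    order = sites.sort_values(["gene_id", "L"]).index
    sites_ord = sites.loc[order]
    gene_slices: dict[str, np.ndarray] = {
        gid: np.flatnonzero((sites_ord["gene_id"] == gid).to_numpy())
        for gid in genes.index
    }

    batches: dict[str, SiteMatrix] = {}
    cell_frames = []
    n_per_type = config.cells_per_type_per_batch
    for b in range(config.n_batches):
        batch_id = f"batch{b}"
        rng = np.random.default_rng([config.seed, 1, b])
        depth = config.depth_factor_per_batch[b]

        jitter = rng.integers(0, config.interval_jitter_max + 1, size=(len(order), 2))
        bsites = sites_ord[["chrom", "start", "end", "strand"]].copy()
        bsites["start"] = bsites["start"] - jitter[:, 0]
        bsites["end"] = bsites["end"] + jitter[:, 1]
        _check_no_cross_site_overlap(bsites, sites_ord["gene_id"])
        bsites.index = pd.Index(
            [f"{batch_id}_{sid}" for sid in sites_ord.index], name="site_id"
        )

        cell_type = np.repeat(types, n_per_type)
        cell_ids = [f"{batch_id}_c{i:05d}" for i in range(len(cell_type))]
        counts = np.zeros((len(order), len(cell_type)), dtype=np.int64)
        base = genes["base_mean"].to_numpy()
        marker_type = genes["marker_type"]
        for ti, t in enumerate(types):
            cols = slice(ti * n_per_type, (ti + 1) * n_per_type)
            mu = base * np.where(marker_type == t, config.marker_fold_change, 1.0)
            mu = mu * depth
            p = theta / (theta + mu)
            totals = rng.negative_binomial(
                theta, p[:, None], size=(len(genes), n_per_type)
            )
            for gi, gid in enumerate(genes.index):
                rows = gene_slices[gid]
                w = shares.loc[sites_ord.index[rows], t].to_numpy()
                counts[np.ix_(rows, range(cols.start, cols.stop))] = rng.multinomial(
                    totals[gi], w
                ).T
        cells = pd.DataFrame(
            {"batch": batch_id, "cell_type": cell_type},
            index=pd.Index(cell_ids, name="cell_id"),
        )
        cells["group"] = cells["cell_type"]
        batches[batch_id] = SiteMatrix(
            counts=sp.csr_matrix(counts), sites=bsites, cells=cells
        )
        cell_frames.append(cells)
    truth.cells = pd.concat(cell_frames)
    return batches


def _check_no_cross_site_overlap(bsites: pd.DataFrame, gene_ids: pd.Series) -> None:
    df = bsites.assign(gene_id=gene_ids.to_numpy()).sort_values(
        ["chrom", "strand", "start"]
    )
    same_key = (
        (df["chrom"] == df["chrom"].shift())
        & (df["strand"] == df["strand"].shift())
    ).to_numpy()
    overlap = (df["start"].to_numpy() < np.roll(df["end"].to_numpy(), 1)) & same_key
    if overlap.any():
        bad = df.index[np.flatnonzero(overlap)[0]]
        raise SynthesisError(
            f"jitter made intervals of distinct sites intersect (near {bad}); "
            "reduce interval_jitter_max"
        )


def expected_metrics(truth: GroundTruth) -> pd.DataFrame:
    """Closed-form expected PPUI and weighted length per (type, gene).

    Restricted to sites the annotation pipeline retains (3'UTR and
    extension); conditional multinomial renormalization makes these
    expectations exact for any positive retained total.  Only APA genes
    (>= 2 retained sites) are listed.
    """
    retained = truth.sites[truth.sites["region_true"].isin(["3UTR", "extended_3UTR"])]
    rows = []
    for gid, gsites in retained.groupby("gene_id", sort=True):
        gsites = gsites.sort_values("L")
        if len(gsites) < 2:
            continue
        L = gsites["L"].to_numpy(float)
        for t in truth.cell_types:
            w = truth.shares.loc[gsites.index, t].to_numpy()
            W = w.sum()
            if W <= 0:
                continue
            rows.append(
                dict(
                    cell_type=t,
                    gene_id=gid,
                    expected_ppui=w[0] / W,
                    expected_length=float((w / W) @ L),
                )
            )
    return pd.DataFrame(rows)


def match_merged_to_truth(truth: GroundTruth, merge_map) -> pd.Series:
    """Map merged site ids back to true site ids.

    Relies on the generator's batch site naming (``<batch>_<true id>``);
    when the jitter respects the inter-site gap every merged site has
    members of exactly one true site.
    """
    members = merge_map.members.copy()
    members["true_site"] = members["site_id"].str.split("_", n=1).str[1]
    per_merged = members.groupby("merged_id")["true_site"].agg(
        lambda s: s.value_counts().index[0]
    )
    return per_merged


def evaluate_depa_calls(
    truth: GroundTruth, depas: pd.DataFrame, merged_to_true: pd.Series
) -> dict:
    """Recall and false-discovery rate of retained DEPAs vs planted truth.

    Recall is over the planted marker-gene sites.  A retained call is a
    false discovery unless it hits a planted DEPA *or* a site of a
    planted APA-shift gene in that gene's target type: shift genes
    genuinely change site expression in their target (that is the
    planted effect), so such calls are differential by construction and
    must not be charged against the detector.
    """
    kept = depas[depas["retained"]] if "retained" in depas else depas
    planted = set(zip(truth.depa_sites.index, truth.depa_sites.values))
    shift_ok = set()
    for gid, row in truth.shift_genes.iterrows():
        for sid in truth.sites.index[truth.sites["gene_id"] == gid]:
            shift_ok.add((sid, row["target_type"]))
    tp = 0
    fp = 0
    for _, r in kept.iterrows():
        true_site = merged_to_true.get(r["feature"], r["feature"])
        key = (true_site, r["group"])
        if key in planted:
            tp += 1
        elif key not in shift_ok:
            fp += 1
    n_called = len(kept)
    return {
        "recall": tp / max(len(planted), 1),
        "fdr": fp / max(n_called, 1),
        "n_planted": len(planted),
        "n_called": n_called,
        "n_false": fp,
    }


def evaluate_apa_marker_calls(
    truth: GroundTruth, apa_markers: pd.DataFrame
) -> dict:
    """Recall of planted shift genes among significant PPUI markers.

    A shortening shift (proximal fraction up in the target type) should
    surface as an up-direction APA marker for that type; lengthening as
    down.
    """
    sig = apa_markers[apa_markers["significant"]] if "significant" in apa_markers else apa_markers
    called = set(zip(sig["feature"], sig["group"], sig["direction"]))
    hits = 0
    for gid, row in truth.shift_genes.iterrows():
        want_dir = "up" if row["direction"] == "shortening" else "down"
        if (gid, row["target_type"], want_dir) in called:
            hits += 1
    n = len(truth.shift_genes)
    return {"recall": hits / max(n, 1), "n_planted": n}


def generate_genome_fasta(
    truth: GroundTruth,
    path: str,
    signal_fraction: float = 1.0,
    seed: int | None = None,
) -> None:
    """Write a random genome with poly(A) signals planted near sites.

    Sequence is uniform random ACGT; for ``signal_fraction`` of the true
    sites the canonical AATAAA hexamer is planted at transcript
    positions −25..−20 upstream of the cleavage coordinate
    (reverse-complemented on '−'), which the nucleotide-composition
    profile can then recover.
    """
    rng = np.random.default_rng(
        [truth.config.seed, 2] if seed is None else [seed, 2]
    )
    lengths: dict[str, int] = {}
    for _, g in truth.genes.iterrows():
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), int(g.gene_end) + 3000)
    chrom_seqs = {
        c: rng.choice(list("ACGT"), size=n).astype("U1") for c, n in lengths.items()
    }
    n_sites = len(truth.sites)
    plant = rng.random(n_sites) < signal_fraction
    for (sid, s), do_plant in zip(truth.sites.iterrows(), plant):
        if not do_plant:
            continue
        seq = chrom_seqs[s.chrom]
        if s.strand == "+":
            lo = s.coord - 25
            seq[lo : lo + 6] = list("AATAAA")
        else:
            lo = s.coord + 20
            seq[lo : lo + 6] = list("TTTATT")
    with open(path, "w") as fh:
        for chrom in sorted(chrom_seqs):
            fh.write(f">{chrom}\n")
            seq = "".join(chrom_seqs[chrom])
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_dataset(
    truth: GroundTruth, batches: Mapping[str, SiteMatrix], out_dir: str
) -> Path:
    """Persist GTF, per-batch MTX trios and truth tables under ``out_dir``."""
    from . import io as io_mod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "genes.gtf").write_text(_to_gtf(truth.genes))
    for batch_id, sm in batches.items():
        io_mod.write_site_matrix(sm, out / batch_id)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    truth.genes.to_csv(truth_dir / "genes.tsv", sep="\t")
    truth.sites.to_csv(truth_dir / "sites.tsv", sep="\t")
    truth.cells.to_csv(truth_dir / "cells.tsv", sep="\t")
    truth.shift_genes.to_csv(truth_dir / "shift_genes.tsv", sep="\t")
    truth.shares.to_csv(truth_dir / "shares.tsv", sep="\t")
    truth.depa_sites.to_frame().to_csv(truth_dir / "depa_sites.tsv", sep="\t")
    return out


def generate_dataset(config: SynthConfig):
    """One-call generation: returns ``(truth, batches, gtf_text)``."""
    gtf, truth = generate_gene_model(config)
    batches = generate_batches(truth, config)
    return truth, batches, gtf
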