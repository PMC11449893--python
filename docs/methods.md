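# Methods

This note documents the models and procedures implemented in
`scapa_atlas`, the parameter choices where the design was genuinely
open, what the synthetic-data generator does and does not emulate, and
the package's known limitations.

## Coordinate conventions

All internal coordinates are 0-based half-open; GTF input (1-based
closed) is converted on read and TSV/BED output is written 0-based
half-open. The **representative coordinate** of a peak — the single
position standing in for the cleavage site — is the strand-aware distal
end of the peak interval: the last covered base furthest downstream in
the direction of transcription (`end − 1` on '+', `start` on '−'). In
1-based coordinates this is exactly "the most distal peak end". The same
convention is applied uniformly to per-batch peaks and to merged sites;
peak callers differ on whether a summit, midpoint or end best represents
the cleavage position, and the distal end is this package's documented
choice, consistent with how merged sites are anchored.

## 3′UTR assignment

A gene model contributes, per protein-coding gene, its annotated 3′UTR
interval and an **extended 3′UTR**: the annotated interval grown 1000 nt
downstream (strand-aware). Genes without a resolvable 3′UTR record get a
zero-length 3′UTR anchored at the stop codon; the extension window still
applies, since the purpose of the extension is precisely to capture
unannotated 3′ ends. A peak is assigned by point containment of its
representative coordinate, on the same strand. Ambiguity between
overlapping genes is resolved by preferring an annotated 3′UTR over an
extension, then the nearest stop codon, then lexicographic gene id —
the stronger annotation wins. Only sites in a (possibly extended) 3′UTR
are retained for APA analysis; the distance L of a site is measured from
its representative coordinate to the gene's stop codon.

## Snowball merging across batches

Peak calling happens per batch, so one biological poly(A) site appears
with slightly different intervals across batches. Within each
(chromosome, strand), peaks of all batches are sorted by start position
and swept once; every peak that shares at least one base with the
growing cluster joins it. Consequences of this definition:

- *Touching is not intersecting*: half-open intervals that merely abut
  stay separate.
- *Transitive chaining*: a chain of pairwise-overlapping peaks collapses
  into one site, so a merged interval can exceed any single peak's
  width. No width cap is imposed; merged sites wider than 1000 nt are
  logged as a warning.
- The merged interval is the member hull `[min start, max end)`; the
  merged id `chrom:strand:start-end` is deterministic; the merged
  coordinate is the strand-aware distal end.

Requantification sums, per merged site and cell, the cell's counts over
the member peaks of its own batch, conserving the grand total exactly.
Embedding-space batch correction (Harmony and kin) is deliberately out
of scope: the statistics downstream operate on counts and ratios, and
embedding correctors do not produce corrected counts. The merged matrix
carries batch labels for any external embedding tool.

## APA metrics

For a 3′UTR-APA gene (≥ 2 retained sites) the proximal site is the one
with the smallest L (ties broken by lowest site id, for determinism).
PPUI is the proximal count over the gene's total 3′UTR count in the
cell; the weighted relative 3′UTR length is the count-weighted mean of
the L values. Two numerical choices matter:

- **No pseudo-counts.** Ratios of small counts are noisy; adding
  pseudo-counts would bias both metrics toward uniform usage. Instead a
  (gene, cell) entry is *missing* unless the gene's total count in that
  cell reaches the defined-threshold `min_gene_count` (default 1,
  configurable — raise it to trade coverage for per-entry precision).
- For 2-site genes the two metrics are affinely linked,
  `L_s = PPUI·L_p + (1−PPUI)·L_d`, which the tests verify to machine
  precision; both are invariant to any positive scaling of a cell's
  counts.

The per-cell PPUI summary is the unweighted mean of the cell's defined
PPUI entries — each covered gene votes once, so deeply covered genes do
not dominate. A count-weighted variant is a documented alternative, but
it answers a subtly different question (usage per read rather than per
gene).

## Marker detection

All three detectors use the Wilcoxon rank-sum test: exact enumeration of
the permutation distribution (mid-ranks, two-sided around the symmetric
mean) when both groups have ≤ 8 observations, otherwise the tie- and
continuity-corrected normal approximation.

**DEPAs** are found Seurat-style on site counts normalized per cell to a
fixed total (10,000) and log1p-transformed — a precisely reproducible
replacement for the invoked tool's default normalization. Candidates
need detection in ≥ 25 % of one side and |logFC| ≥ 0.25, where logFC is
the natural log of the ratio of group means of de-logged normalized
values plus one (the invoked tool's convention). P-values are
Bonferroni-adjusted over the tests actually performed; the final DEPA
set keeps up-regulated candidates with adjusted p < 0.05 detected in
> 20 % of the target group and < 20 % of the rest. The detection
fractions are computed on raw detection (count > 0), the natural reading
of an "expression ratio" filter on sparse counts.

**APA markers** test each gene's defined PPUI values one-vs-rest (or
pairwise); **switching genes** test the weighted length between two
named groups, with direction lengthening in the first group when its
mean length is higher. Both default to Benjamini–Hochberg FDR < 0.05
(configurable to Bonferroni): thousands of genes are tested and the
Bonferroni convention above is specific to the DEPA stage. A gene needs
≥ `min_cells` (default 10) defined cells on each side to be tested;
untested genes are reported as such. Direction uses the difference of
group means, matching the weighted-average character of the length
metric.

## Cell typing

Consensus: a cell is labeled when at least two strategies agree (the
unique modal label with support ≥ 2); ties and single votes leave it
unlabeled. The reference profile is the per-type mean log-normalized
expression over the top-200 highly variable genes — one *global* HVG
ranking by variance of log-normalized expression across labeled cells
(a per-type union mode is available). Unlabeled cells get three votes:

1. Pearson correlation to the reference profiles (zero-variance cells
   abstain),
2. argmax AUC activity of per-type DEPA site sets on the cell's site
   counts, and
3. argmax AUC activity of per-type APA-marker gene sets on the cell's
   PPUI values (missing values rank last).

AUC activity ranks the cell's features by decreasing value — ties broken
by a seeded random permutation, recorded in the run config — and
integrates the set-recovery curve inside the top `top_fraction` of
ranks, normalized by its maximum attainable area, giving a rank
statistic in [0, 1] invariant to monotone transforms. `top_fraction`
defaults to 0.05 (the convention of the tool that popularized the
score); with feature spaces of only a few hundred sites the 5 % window
spans a few dozen ranks dominated by count ties, so desk-scale analyses
in this package use 0.2 — the parameter is explicit everywhere.

The majority of the three votes wins; when all three differ the
DEPA-based vote is used (APA site expression is the layer closest to the
data here). A generic low-support relabeling rule (`relabel_low_support`)
re-assigns cells whose designated label is carried by fewer than two of
the available label sources to a designated fallback — mirroring the
re-annotation of weakly supported quiescent-center calls to
stem-cell-niche. Expression matrices are filtered iteratively to a fixed
point: cells with ≥ 200 expressed genes and genes in ≥ 3 cells per
batch, ≥ 500 and ≥ 5 for a combined matrix (both overridable; synthetic
desk-scale runs use smaller values since they carry only a few hundred
genes).

## The synthetic compendium

The generator plants a known truth and emulates the structural features
the pipeline must cope with:

- **Gene models**: non-overlapping genes on both strands of two
  chromosomes, each with a 300-nt CDS, a stop codon and an annotated
  3′UTR; 1–3 poly(A) sites per gene at distances drawn from
  `utr_length_range` on a grid whose spacing guarantees that maximally
  jittered intervals of distinct sites never intersect. Controllable
  fractions of genes carry an extra site inside the 1000-nt extension
  window or beyond it, to exercise the extension and discard rules.
- **Counts**: a cell's gene total is negative binomial with mean =
  base expression × marker fold (if the gene marks the cell's type) ×
  batch depth factor, dispersion θ (variance μ + μ²/θ); the total is
  split over the gene's sites by a multinomial with proximal probability
  π(type, gene) and the rest uniform over distal sites. Because
  multinomial proportions are conditionally unbiased, π is the *exact*
  expected PPUI and Σ(wᵢ/W)Lᵢ the exact expected weighted length over
  any retained-site subset — the closed-form oracles the tests use.
- **Planted effects**: shift genes change π in one target type
  (0.8 vs 0.3 by default, alternating shortening/lengthening); marker
  genes are multi-site, lowly expressed off-target (gene mean 0.3) with
  fold 4 in their type, and use a uniform site allocation so the fold is
  a clean per-site detection contrast — the regime in which the 20 %/20 %
  DEPA retention rule is satisfiable at all. Marker and shift genes are
  disjoint; a site of a shift gene is genuinely differentially expressed
  in its target type, and planted-truth evaluations account for that.
- **Batches**: per-batch depth factors (1.0, 1.5, 0.7 by default) and
  per-batch outward jitter of both interval boundaries, uniform in
  [0, `interval_jitter_max`]. Outward-only expansion is what guarantees
  that intervals of the same true site always intersect across batches;
  the generator verifies that distinct-site intervals never do.
- **Dispersion**: θ = 10 by default — near-Poisson measurement noise
  with cell-type structure (markers, shifts) as the dominant source of
  biological variance, which is the premise of HVG selection. θ is a
  single global knob; real data mix dispersions per gene.
- Default scale: 4 cell types × 200 cells per type per batch × 3
  batches, 200 genes (marker studies in the tests use 400 genes with
  ~200 cells per type) — sizes chosen so every planted-truth check has
  adequate power on a single CPU while the full suite stays fast.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: ambient RNA, doublets, UMI
errors, internal-priming artifacts, per-gene dispersion heterogeneity,
correlated gene programs, continuous differentiation trajectories, and
genome sequence realism beyond planted AATAAA hexamers for the
nucleotide-composition profile. Real peak callers also produce
width-varying, coverage-dependent peaks; the generator's fixed-width
peaks with bounded jitter are the idealization under which exact jitter
recovery is provable.

## Determinism

One root seed drives named substreams (gene layout, per-batch counts,
genome sequence, AUC tie-breaks), so identical configuration and seed
reproduce every output file byte for byte; the pipeline's structured log
deliberately carries no timestamps. Tie-breaks anywhere in the package
(proximal site, annotation ambiguity, ranking) are resolved by fixed
documented rules, never by iteration order.

## Known limitations

- Intronic/internal APA sites are out of scope by design: only (extended)
  3′UTR sites are analysed.
- The snowball merge is greedy and transitive; dense peak landscapes can
  chain distinct sites into one cluster. The warn threshold surfaces
  this; no splitting heuristic is applied.
- Wilcoxon one-vs-rest treats cells as exchangeable; batch is not a
  covariate in the tests (the synthetic depth factors cancel in the
  rank tests and in the per-cell-normalized DEPA analysis, but real
  batch effects need not).
- `pcc_annotate` assigns the argmax correlation without a confidence
  margin; closely related types can flip on noise.
- The index-of-cell-identity and clustering-based annotation strategies
  are consumed as externally supplied label columns, not computed here.
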