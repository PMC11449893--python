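# scapa-atlas

Toolkit for analysing **alternative polyadenylation (APA) at single-cell
resolution** from 3′-tag scRNA-seq poly(A)-site count matrices. It is aimed
at anyone who has per-batch poly(A)-site peak matrices (e.g. from a peak
caller such as scAPAtrap) for a multi-sample single-cell atlas — the
motivating system is the Arabidopsis root — and wants to:

1. assign peaks to gene 3′UTRs (with the standard 1000-nt downstream
   extension) and discard everything else,
2. merge peak lists across batches into one unified poly(A)-site map and
   requantify every cell against it,
3. quantify APA per gene per cell,
4. find cell-group APA markers of three kinds, and
5. use the APA layer to refine cell-type annotation.

## The quantities at the core

For a 3′UTR-APA gene (a gene with ≥ 2 poly(A) sites in its extended
3′UTR) with site read counts $E_{i,s}$ in cell $s$ and site-to-stop-codon
distances $L_i$:

- **PPUI** (proximal poly(A)-site usage index), with $p$ the proximal site:

$$\mathrm{PPUI}_s = \frac{E_{p,s}}{\sum_i E_{i,s}} \in [0,1]$$

  High PPUI = preferential proximal cleavage = short 3′UTR.

- **Weighted relative 3′UTR length**:

$$L_s = \frac{\sum_i E_{i,s}\,L_i}{\sum_i E_{i,s}}$$

Three marker classes are detected with one-vs-rest / pairwise Wilcoxon
rank-sum tests: **DEPAs** (differentially expressed poly(A) sites, on
normalized site counts, Bonferroni-adjusted, with detection-fraction
filters min.pct = 0.25, |logFC| ≥ 0.25, detected > 20 % inside and < 20 %
outside the group), **APA markers** (on PPUI), and **APA switching genes**
(on $L_s$ between two named groups, with a lengthening/shortening
direction).

Cell typing combines independent annotation strategies by consensus
(≥ 2 strategies agreeing), builds a top-200-HVG reference profile from
labeled cells, and re-annotates unlabeled cells by the majority of three
votes — Pearson correlation to the reference, AUC activity of per-type
DEPA site sets, and AUC activity of per-type APA-marker gene sets — with
the DEPA vote breaking three-way disagreements.

A fully tested synthetic-data generator (`scapa_atlas.synth`) emulates a
multi-batch compendium with planted cell types, marker genes, APA-shift
genes, per-batch depth differences and per-batch peak-boundary jitter, so
the whole pipeline is verifiable against known ground truth.

## Worked example

```python
import scapa_atlas as sa

cfg = sa.SynthConfig(n_genes=100, cells_per_type_per_batch=50, seed=0)
truth, batches, gtf = sa.generate_dataset(cfg)
open("genes.gtf", "w").write(gtf)

model = sa.load_gene_model("genes.gtf")
merged, mm = sa.merge_and_requantify(batches, model=model)
merged = merged.subset_sites(
    merged.sites.index[merged.sites["region"].isin(["3UTR", "extended_3UTR"])]
)
index = sa.build_apa_index(merged.sites)
ppui = sa.ppui(merged, index)
labels = merged.cells["cell_type"].astype(str)
depas = sa.find_depas(merged, labels)
apa = sa.find_apa_markers(ppui, labels)
```

Output of the accompanying script (three batches of 50 cells per type ×
4 types, uneven depth, ±5 nt peak jitter):

```
202 merged sites from 606 batch peaks; 600 cells
75 3'UTR-APA genes
DEPAs retained: 26 of 117 tested
APA markers (FDR<0.05): 40 of 300 tests
switching genes type0 vs type1: 6 (0 lengthening, 6 shortening in type0)
per-cell PPUI summary by type:
type0    0.369
type1    0.319
type2    0.359
type3    0.331
```

The 606 batch peaks collapse to 202 merged sites — exactly the number of
distinct planted sites, because the per-batch jitter stays below the
inter-site gap. The retained DEPAs are the sites of the planted marker
genes; the APA markers and switching genes recover the planted
proximal-usage shifts (type0's shift genes in this run were all planted
as shortening). The per-cell PPUI summary is the mean PPUI over each
cell's covered APA genes.

The same stages are available from the shell:

```bash
scapa-atlas synth --out data --seed 3 --n-genes 40 --cells-per-type 15
scapa-atlas integrate --batch data/batch0 --batch data/batch1 \
    --batch data/batch2 --gtf data/genes.gtf --out merged
scapa-atlas metrics --matrix merged --which ppui --out ppui.tsv
scapa-atlas markers --matrix merged --kind depa --out depas.tsv
scapa-atlas run --config pipeline.yaml
```

## Layout

- `src/scapa_atlas/synth.py` — synthetic compendium generator + oracles
- `src/scapa_atlas/annotate.py` — 3′UTR assignment, extension rule,
  nucleotide-composition profiles
- `src/scapa_atlas/integrate.py` — snowball merge, requantification
- `src/scapa_atlas/metrics.py` — PPUI, weighted 3′UTR length, gene-level
  aggregation, per-cell summary
- `src/scapa_atlas/markers.py` — DEPAs, APA markers, switching genes
- `src/scapa_atlas/celltyping.py` — consensus, reference profiles, AUC
  activity, refinement
- `src/scapa_atlas/io.py`, `pipeline.py`, `cli.py` — formats, driver, CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
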