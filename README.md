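# nbconform

Nuclear bodies such as Cajal bodies (CBs) sit at hubs of genome
organisation: a single viewpoint locus (e.g. the *RNU1* snRNA gene
cluster) contacts small-RNA and histone gene loci across chromosomes, and
those contacts can be probed by 4C-seq, by high-content DNA FISH /
immunofluorescence imaging, and by the transcriptional consequences of
disassembling the body. `nbconform` is a reusable, tested implementation
of that analysis stack for researchers studying nuclear-body-associated
genome conformation:

- **4C-seq contact profiling** (`nbconform.fourc`): demultiplexing,
  bait trimming and truncation of raw reads to 50 nt; counting mapped
  reads into non-overlapping 10 kb bins; pooling replicates; running
  100 kb window averages assigned to bin centres with a 0.1 pseudocount
  before log2; contact regions as maximal runs of bins with log2 signal
  strictly above 7.
- **Contact-gene sets and enrichment** (`nbconform.contact_genes`):
  region extension (±10/25/50 kb), gene assignment by the midpoint rule,
  a 4C-positive set filtered to the top 5% of expression, a 4C-negative
  control set >50 kb from any contact, and an empirical enrichment test
  against 100 random interval sets matched in count, length and
  chromosome, with p = (1 + #{null ≥ obs}) / (1 + N).
- **FISH/IF spot analysis** (`nbconform.imaging`): maximum projection,
  nuclear segmentation with border exclusion, brightest-pixel spot
  centres, per-RNU1-spot minimum distances, and the threshold
  classification — CB-dependent pairing when d(gene, gene) ≤ 3 px
  (0.96 μm at 320 nm/px) and d(gene, CB) ≤ 5 px (1.6 μm); CB-independent
  when the CB distance exceeds 5 px; CB bridging as an orthogonal flag.
  Interaction frequency is the percentage of eligible cells (≥1 spot per
  channel) carrying at least one event.
- **Geometric null** (`nbconform.geometry`): the chance level for
  body–territory association from 2D-projected areas, r = √(area/π) and
  P = ((CT_rad + Δ)/NUC_rad)², with a Monte-Carlo placement oracle.
- **Expression calls** (`nbconform.expression`): FPKM, log2 replicate
  averaging, the two-control concordance rule (a change counts only
  against both the untreated and the mock-treated control), quartile
  binning, and 2^−ΔΔCt qPCR fold changes.
- **Splicing noise** (`nbconform.splicing`): exact-match junction
  annotation status, condition-unique junction sets, per-gene
  unannotated-junction summaries, depth/FPKM-normalized detection
  metrics, PSI and ΔPSI, and a two-sided Fisher exact test.
- **Synthetic data with planted truth** (`nbconform.synthetic`): seeded
  generators for every input — 4C reads with bait-centred distance decay
  and planted contact peaks, barcoded raw reads, cell populations with
  planted CB-dependent/-independent pairing rates (optionally rendered to
  images), log-normal expression with planted knockdown effects, and
  junction tables with planted noise rates — so every downstream stage
  has a recoverable answer.

The full chain runs end to end on synthetic data via
`nbconform.pipeline.run_pipeline` or the `nbconform` CLI.

## Worked example

```python
from nbconform import fourc, imaging, synthetic

genome = synthetic.default_genome()
arch = synthetic.default_architecture(genome)        # 2 cis + 1 trans peak, 50x
reads = synthetic.simulate_4c_reads(arch, genome, 100_000, seed=1)
tracks = fourc.bin_reads(reads, genome)              # 10 kb bins
for chrom in sorted(tracks):
    profile = fourc.smooth_and_log(tracks[chrom])    # 100 kb window, +0.1, log2
    for region in fourc.call_contact_regions(profile, threshold=7.0):
        print(chrom, region.interval.start, region.interval.end,
              round(region.peak_value, 2))
```

prints

```
chr1 660000 1340000 11.98
chr1 1950000 2100000 9.97
chr1 3160000 3290000 8.89
chr2 960000 1090000 9.02
```

— the viewpoint-proximal block around the bait at 1 Mb plus one called
region over each planted peak (cis at 2.0 and 3.2 Mb, trans at 1.0 Mb on
chr2), with peak smoothed log2 signals of 9–12 against a sub-threshold
background. Continuing with imaging:

```python
cells = synthetic.simulate_cell_spots(
    synthetic.CellPopulationModel(n_cells=2_000, p_dep=0.3, p_indep=0.1),
    seed=2,
)
pct, se, n = imaging.interaction_frequency(
    [c.table for c in cells], lambda label, bridging: label == "CB_dependent"
)
print(f"{pct:.2f}% +/- {se:.2f} (n={n})")   # -> 28.95% +/- 1.01 (n=2000)
```

recovering the planted 30% CB-dependent pairing rate within sampling
error.

A complete synthetic run with all artifacts (bedGraph profiles, BED
region and gene sets, enrichment/frequency/differential/splicing/geometry
reports):

```bash
nbconform run --out demo_run --seed 1
```

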