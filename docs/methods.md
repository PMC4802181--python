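# Methods

This note documents the models, parameter choices and numerical
conventions behind `nbconform`, and what the synthetic-data generators do
and do not emulate.

## 4C contact profiling

Mapped reads are counted into non-overlapping bins (default 10 kb) by
**overlap**: a read increments every bin it intersects, so a
boundary-spanning read is counted twice. The alternative (5′-position
counting) is deliberately not used; overlap counting follows the stated
procedure literally, and the conservation property is therefore
`sum(bin counts) ≥ n_reads` with equality only when no read spans a
boundary.

Smoothing assigns to each bin centre the mean of counts over bins whose
centres lie within ±window/2 (default window 100 kb ⇒ 11 bins of 10 kb in
the interior; a "100 kb window" is ambiguous between 10 and 11 bins, so
the window is a parameter and the centred 11-bin reading is the default).
Chromosome ends use the truncated window — the mean over however many
bins actually exist — rather than padding, which would invent signal. A
pseudocount of 0.1 is added before log2, so an all-zero neighbourhood
maps exactly to log2(0.1).

Contact regions are maximal runs of bins with smoothed value strictly
above the threshold (default 7 log2 units, comparison `>`), merged across
adjacency only. Re-calling on the same profile is idempotent and the
output is sorted and disjoint.

Raw-read preprocessing demultiplexes on prefix-free barcodes, strips
barcode + bait primer, truncates to the first 50 nt, and applies a
quality filter of mean phred ≥ 20 (configurable; the source procedure
says only "quality filtering", so the Q20 mean is this package's
concrete reading). Rejections are logged with reasons
(`too_short` / `no_barcode` / `no_bait` / `low_quality`).

## Contact genes and permutation enrichment

Called regions are extended symmetrically (±10, 25 or 50 kb), clipped to
chromosome bounds and merged. A gene belongs to a region iff its
**midpoint** (floor of (start+end)/2) lies inside; an intersectBed-style
50%-overlap rule (`min_overlap_fraction=0.5`) is available as an option,
the midpoint rule being the primary definition. The 4C-positive set intersects the midpoint
hits with genes at or above the nearest-rank 95th percentile of
expression over *all* genes (ties at the threshold kept inclusively — the
reproducible choice without an arbitrary tiebreak). The 4C-negative set
takes the same expression filter but requires an edge-to-edge distance
greater than 50 kb from every contact region; the two sets are disjoint
by construction.

Enrichment of target gene classes (snRNA, snoRNA, scaRNA, histone;
proximity 10 kb) is tested against 100 random interval sets matching the
observed regions in count, length and chromosome (genome-wide placement
is a flag), placed uniformly without overlap among themselves. The
empirical p uses the +1 correction, p = (1 + #{null ≥ obs})/(1 + N), so
its floor is 1/(N+1) and it can never be 0. Because the statistic is a
count, ties between null and observed values make the test conservative;
the calibration suite asserts the null rejection rate at α = 0.05 inside
a band whose upper edge is the attainable level 5/101 plus three binomial
standard errors and whose lower edge allows that conservativeness. Toy
genomes contain no assembly gaps, so no gap exclusion is implemented (a
placement flag is reserved for it).

In the end-to-end pipeline the called region containing the bait is
excluded before gene-set construction and enrichment: in any single-
viewpoint contact assay the viewpoint-proximal signal is dominated by
self-ligation and would otherwise swamp the matched null.

## FISH/IF spot analysis

Stacks are maximum-projected per channel. Nuclei are segmented from the
projected nuclear stain by a global Otsu threshold (an explicit threshold
can be given), hole filling, connected-component labelling and a minimum
area filter; components touching the image border are flagged and
excluded from statistics. Spot detection finds 8-neighbourhood intensity
local maxima above a minimum intensity inside the nucleus, suppresses
candidates closer than `min_separation` (default 2 px) greedily in order
of decreasing intensity, and breaks exact intensity ties toward the
smallest (y, x). Proprietary high-content-platform scripts used for such
screens are not public, so the deterministic contract (disc nuclei
recovered, border exclusion, the tie rule) is what the tests pin down.
The brightest pixel of each signal is its centre.

Distances are 2D Euclidean in pixels, computed on continuous coordinates
when spots come from tables and on integer pixel centres when detected
from images. Eligibility requires ≥1 spot in each of the three channels
(RNU1, the variable gene of interest VGOI, and the CB marker). Per RNU1
spot: d_gene = min distance to any VGOI spot, d_cb = min distance to any
CB; the CB realizing d_cb supplies its own minimum CB–VGOI distance for
the bridging flag (using any CB is a flag). Classification at 320 nm
pixels: CB-dependent iff d_gene ≤ 3 px and d_cb ≤ 5 px; CB-independent
iff d_gene ≤ 3 px and d_cb > 5 px (strict, reading the distal condition
literally); bridging iff d_cb ≤ 5 px and d_cb_vgoi ≤ 5 px, reported
orthogonally to the pair label. Interaction frequency is the percentage
of eligible cells with ≥1 qualifying event (events are not weighted
beyond the ≥1 rule); ineligible cells leave both numerator and
denominator.

Locus position relative to a projected territory mask uses Euclidean
distance transforms: interior beyond `edge_width` inside the mask,
periphery within ±`edge_width` of the boundary, exterior beyond it. This
is a simplification of published erosion-shell scoring schemes;
near-boundary discretization (≲1 px) is inherent
and the oracle tests exclude a 1.5 px shell.

## Geometric null

Radii come from projected areas as r = √(area/π). The chance association
level treats nucleus and territory as concentric discs: a body centre
uniform in the nuclear disc is associated iff it falls within edge
distance Δ of the territory, giving P = min(1, ((CT_rad + Δ)/NUC_rad)²).
The concentric form is the package's default model; a
uniform-containment territory placement is available in the Monte-Carlo model (`concentric=False`) and
is bounded above by the concentric form since part of the association
halo is clipped by the nuclear boundary. The closed form and the
Monte-Carlo oracle agree within 3 binomial s.e. at 10^6 draws across a
parameter grid. Radii and Δ must share one length unit; the probability
is invariant under joint rescaling.

## Expression calls

FPKM = count / ((length/10³)(mapped/10⁶)). Replicates are averaged on the
log2 scale after adding a pseudocount (default 0.01, recorded in output
metadata; distinct from the 4C profile pseudocount of 0.1), making the
per-condition value the log of a geometric mean. A knockdown gene is
called decreased iff its log2 value sits at least `lfc_threshold` below
**both** controls (untreated and mock-treated), increased symmetrically,
else unchanged. No canonical fold-change cutoff exists for such a
concordance rule, so the default threshold is 1 log2 unit, exposed as a
flag; at the
default generator noise this yields a null false-positive rate below 5%
and ≳90% recall of −2 log2 planted effects (genes expressed below the
pseudocount are compressed toward it and set the detection floor).
Dispersion-based differential machinery (DESeq-style) is intentionally
not reimplemented: the concordance rule itself is the method under test.
Quartile binning uses nearest-rank cuts with ties kept in the upper bin.
qPCR fold change is 2^−ΔΔCt with ΔCt = Ct_target − Ct_reference per
condition; swapping conditions inverts the fold change exactly.

## Splicing noise

Junctions are keyed (chrom, donor, acceptor, strand); annotation status
is exact-match lookup, so a 1 bp shift is unannotated. "Detected" means
count ≥ min_count (default 1, exposed because uniqueness counts are
sensitive to it); a junction is unique to a condition group iff detected
in ≥1 member and in no member of the other group (requiring all members
is a flag). Junction→gene assignment is by full containment; junctions in
no gene report as `intergenic`, in several as `ambiguous`. The
depth/expression normalization metrics implement the four printed
formulas exactly, with undefined ratios returned as NaN, never silent
zeros. PSI = inclusion/(inclusion+exclusion), NaN for 0/0, propagating
through ΔPSI. The two-sided Fisher exact test uses the probability-mass
definition (sum of tables with hypergeometric probability ≤ observed),
via scipy, cross-checked in the tests against exact-rational enumeration.

## Synthetic-data generators

The data being emulated carry no canonical distributional forms, so all
forms here are package choices, selected to be the simplest that leaves each
planted parameter recoverable:

- **4C reads**: per-1 kb-segment sampling weights; on the bait chromosome
  w ∝ (d/1 kb)^−α with the bait distance floored at 1 kb (α = 1 default;
  the floor avoids the viewpoint singularity), on other chromosomes a
  uniform `trans_level` (default 5×10⁻⁴ of the floor-distance cis
  weight, making contacts predominantly intra-chromosomal); peaks
  multiply the local weight by their enrichment factor (default 50×,
  50 kb). Exactly n_reads of 50 bp are drawn multinomially. With α = 0,
  no peaks and trans_level 1 the density is genome-wide uniform, which
  the chi-square suite verifies.
- **Cell populations**: each cell draws a label
  (dependent/independent/none) with probabilities (p_dep, p_indep, rest),
  then spots are rejection-sampled in the nuclear disc honouring the
  label: a dependent cell plants an RNU1–VGOI pair ≤ 3 px with a CB
  within 5 px; an independent cell plants the pair with every CB beyond
  5 px; background alleles keep a 0.5 px guard band clear of the
  thresholds so the planted label is exactly the downstream
  classification and rate recovery is a pure binomial experiment. Every
  cell has ≥ 1 CB (1 + capped-Poisson extras, mean 1.5, matching
  imaged CB-per-cell histograms being concentrated at 1–3) so all cells
  are analysis-eligible. Nuclei are discs (radius ~N(40, 4) px,
  floored); a nucleus that cannot host its constraint set within the
  retry budget is regenerated, never silently accepted. Rendering draws
  Gaussian spots (σ = 1 px) plus optional Poisson noise on a disc
  nuclear stain.
- **Expression**: per-gene baseline log2 FPKM ~ N(3, 4.5) (a ~8-order-of-
  magnitude dynamic range), knockdown shift applied only to genes flagged
  CB-proximal (10% by default), independent N(0, 0.5) replicate noise,
  duplicate replicates per condition; counts are back-computed from FPKM
  at fixed length (1 kb) and depth (10⁷).
- **Junctions**: per gene, a fixed evenly spaced annotated set (3 per
  gene) with Poisson counts tied to depth × expression link; unannotated
  junctions per gene per condition ~ Poisson(rate) (defaults 0.1 control
  / 0.2 knockdown) at coordinates inside the gene that never collide
  with the annotated set.
- **Splicing events**: inclusion ~ Binomial(depth, PSI) at planted PSI
  per condition.

Each generator consumes its own RNG stream split deterministically from
the seed (stage-name keyed), so stages are individually and bitwise
reproducible.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: restriction-fragment structure, mappability and
assembly gaps, sequencing error, 3D nuclear geometry and optical
z-resolution, spot clustering beyond the planted configurations,
expression dispersion structure (gene-length and GC effects), and
annotation incompleteness beyond exact-match misses. Statistical
guarantees verified here (calibration, recovery within binomial error)
transfer to real data only insofar as those effects are secondary to the
quantities tested.

## Problem sizes and numerical choices

Default synthetic scale: a 6 Mb two-chromosome genome, 10⁵ reads per 4C
replicate, 2,000 cells for rate recovery, 1,000 genes for expression
calibration, 10⁶ draws for the geometric oracle, 1,000 runs × 100
permutations for null calibration — sizes at which every statistical
criterion resolves comfortably on a single CPU in seconds to tens of
seconds. Thresholds are compared exactly as defined (strict `>` for the
4C threshold and the CB-distal condition, `≤` for inclusion bounds);
quantile and quartile cuts use nearest-rank with inclusive ties;
degenerate inputs (zero-variance correlation, 0/0 PSI, zero FPKM
denominators, empty margins) return explicit NaN or raise, never a
silent zero.

## Known limitations

The imaging stage models 2D projections only; true 3D distances are out
of scope. The permutation null matches interval count and length but not
local gene density. The locus-position classifier is a simplification of
the published erosion-shell scheme. The concordance rule is a
thresholding heuristic, not a calibrated hypothesis test — its
false-positive behaviour is characterised empirically under the
generator's noise model. Real-data headline counts (numbers of
differential genes, unannotated junction totals, observed association
percentages) depend on real sequencing depth, annotation and imaging
calibration and are deliberately not targets of the synthetic suite.
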