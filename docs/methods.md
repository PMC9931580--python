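# Methods notes

This note records the modelling choices, conventions and numerical
decisions behind `cytoniche`, and what the synthetic validation studies do
and do not demonstrate.

## Coordinate and data conventions

Pixel units with 1 µm/pixel by default (so a 6-pixel adjacency radius is
6 µm); origin top-left, x = column, y = row, 0-based. Cell centroids are
unweighted means of member-pixel coordinates, matching label-mask
regionprops conventions. Per-cell expression is the mean raw pixel value
per channel; no arcsinh or log transform is applied anywhere in the
statistics — the 95th-percentile normalization and z-scored cluster means
exist only for display. Channels are matched to panels by name from TIFF
metadata; order-based matching requires an explicit flag because silent
channel-order mismatches are the dominant failure mode for these panels.

## Mask curation

The per-marker recipe is median filter (3×3, edge replication) →
6-level 1-D k-means quantization → brightest-L-group selection → removal of
8-connected blobs smaller than `min_blob_area` (default 4 px²) → optional
adaptive refinement → with optional percentile contrast enhancement as a
pre-step. Decisions the recipe leaves open, fixed here:

- **"Brightest L groups."** Foreground selection counts from the brightest
  intensity group down, since antibody signal is bright-positive. Group
  centres are stored in ascending order so the opposite convention is a
  one-line change.
- **Quantization.** k-means with k-means++ init and 10 restarts at a fixed
  seed for determinism. Above 200k pixels the centres are fitted on an
  evenly strided subsample of the sorted values; pixel assignment is always
  exact (sorted-centre midpoint boundaries). Degenerate channels with
  fewer distinct values than k get one group per value; a constant channel
  yields an empty mask (a single intensity group carries no signal to
  separate).
- **Choice of L.** The level is a per-channel curation parameter. For the
  synthetic marker model (lognormal signal, µ = 3, σ = 0.5 on the log
  scale, over exponential background with mean 0.3) the high-variance
  signal range attracts five of the six k-means centres, so the synthetic
  panels use L = 5 — all signal groups, background group excluded — which
  recovers planted regions with sensitivity ≈ 0.99 at false-positive rate
  ≈ 0. Dimmer or noisier channels need a different L, exactly as manual
  curation does on real panels.
- **Adaptive refinement.** The threshold is the local mean over a square
  window of side `2·floor(min(H, W)/16) + 1`, scaled by sensitivity *s* as
  `T = (1.5 − s)·local_mean` (s = 0.5 neutral; larger s admits more
  foreground); the refinement mask is intersected with the input mask
  (union available), making the step a strict refinement.

## Lineage assignment

A lineage's score is the **maximum** of its defining markers' counts, not
the sum, so multi-marker lineages do not double-count co-stains. Ties go to
the earlier hierarchy entry; the shipped default ordering (tumour > vessel >
lymphoid > myeloid > astrocyte in user configs) is a convention — the
hierarchy is always a required, user-supplied config. Subphenotype
positivity calls use mask overlap of at least 25% of the cell's area
(default), robust to mask speckle while catching partial membrane staining;
a mean-intensity cutoff is available as an alternative through custom
rules. Undefined cells keep their expression summaries and participate in
all spatial analyses as their own category.

## Interaction permutation test

The statistic for an ordered pair (A, B) is the mean B-neighbour count per
A-cell within 6 µm, directional by construction (row-to-column). The null
permutes phenotype labels over **all** cells of the image, positions and
graph fixed; Undefined cells are shuffled with the rest because they occupy
space. The (1 + c)/(n + 1) p-value estimator avoids zero p-values; interact
and avoid calls are mutually exclusive because the two tails share tie
mass. Two practical consequences of the contact-count statistic at tissue
densities:

- At ~500 cells/mm² the null contact count between two of three equal
  types is a small integer (mean ≈ 3), so the permutation p-values are
  conservative and the realized two-tail type-I error at α = 0.01 sits
  near 0.01 rather than 0.02.
- Hard-core avoidance removes the cross-pair edges from the graph itself;
  the conditioned null then expects few cross contacts, and at sparse
  densities an observed zero is simply not exceptional. Detecting planted
  avoidance therefore requires realistic density — the power study uses
  the generator default of 2,000 cells/mm², where an 8 µm hard core is
  called in ~100% of images, while at 500 cells/mm² no test based on this
  null can call it (a property of the design, not the implementation).

Per-image seeds are derived by hashing (master seed, image id, purpose), so
results are independent of execution order and worker count.

## Cellular neighbourhoods

Windows exclude the index cell ("N closest cells *to* a cell"); inclusion
is a flag. Frequencies rather than counts are clustered so models with
different N share one space. Exact distance ties at the window boundary are
broken by row order for reproducibility. Mini-batch k-means uses batch
size 100 and seed 0 by default (batch 1024 suits larger cohorts); fitted
labels are 1-based. Prevalence is exact (percentages summing to 100 per
image) and patient-level prevalence averages duplicate cores before any
survival stratification. The z-split places z = 0 in the high group; the
median split places the median value in the high group.

## Hybrid clustering

DBSCAN (eps 3, minPts 30) runs on the 2-D embedding by default — the eps
scale matches embedded coordinates, and a flag allows feature-space
operation. The single largest DBSCAN cluster is the "big" group re-clustered
spectrally (k-NN affinity graph, k = 15, symmetric normalization) on a
1-in-10 uniform seeded subsample; the number of spectral clusters is a
required parameter with an eigengap heuristic as `"auto"`. The final 5-NN
completion classifies only unlabelled points, so committed labels never
change and the completion step is idempotent; noise points are absorbed
rather than orphaned.

## Survival and group statistics

Parametric tests are used when every group passes Shapiro–Wilk at 0.05 or
when every group has ≥ 30 values (the large-sample override; the threshold
is configurable). More than two groups use one-way ANOVA with Tukey
pairwise comparisons, or Kruskal–Wallis on the rank branch. Patients alive
at last follow-up are treated as censored at that date. Log-rank is the
standard Mantel–Cox chi-square (1 df for two groups).

## Synthetic tissue generator

Defaults emulate ~1 mm² cores at 1 µm/pixel with 2,000 cells (inside the
observed 1,000–5,000 per image), cells as disjoint discs of radius 3–5 px,
per-type lognormal marker signal over exponential background mimicking ion-
count skew. Planted structure:

- **Attraction**: a Thomas cluster process — a strength fraction of B
  cells re-placed as Gaussian offspring (s.d. = scale) of uniformly chosen
  A cells.
- **Avoidance**: Matérn-II-style hard-core thinning of B within the scale
  distance of any A (realized counts drop accordingly).
- **Niches**: quadrant or vertical-band regions with distinct type
  compositions. The shipped `dominant_compositions` puts 0.9 on the
  region's own type: a 3-cell window then identifies its region with
  probability ≈ 0.97 (P[Bin(3, 0.9) ≥ 2]), so planted niches stay
  recoverable across the whole window-size sweep, while quadrant-boundary
  cells remain genuinely ambiguous.
- **Survival**: exponential times with hazard log-linear in the patient's
  standardized planted niche prevalence, administratively censored at
  5 years; 1–2 cores per patient. The power study uses a case-control
  cohort (`feature_distribution="two-level"`, 16 low + 16 high patients),
  mirroring extreme-survivor designs; a uniform latent feature gives the
  same null calibration but a binary z-split of it dilutes power to the
  detection boundary.

What the generator does **not** emulate: realistic cell morphologies
(segmentation is out of scope; discs only exercise pixel-level voting),
marker spillover and isotope impurity, staining artefacts or batch effects,
shared markers between lineages (each planted type has one defining
marker), and 3-D tissue. Passing validation therefore demonstrates the
correctness and calibration of the algorithms under their stated
assumptions — not robustness to segmentation error or spectral noise on
real cores. Note that rendering enforces disjoint discs, which erases
sub-6-µm centroid structure; interaction studies run on the point-pattern
layer, phenotyping studies on rendered rasters.

## Validation problem sizes

The studies run at: 500 null images (500 cells, 3 types, 1,000
permutations) for calibration; 100 images per planted interaction mode;
100 random 12×12 instances for the vote oracle; 20 rendered
360×360 µm cores at 500 cells (≈ 3,900 cells/mm²) with 8 lineages for
end-to-end phenotyping; 40 default-size images for CN recovery across
N ∈ {3, 5, 10, 20, 30}; 300-point planted groups for hybrid clustering;
and 200 null + 100 hazard-linked 32-patient cohorts for the survival
machinery. These sizes give Monte-Carlo error comfortably inside each
study's decision band while keeping a full run around two minutes on one
CPU.

## Known limitations

- The interaction statistic is asymmetric and conditioned on one image;
  cohort-level permutation nulls and distance-decay models are out of
  scope.
- Mini-batch k-means trades exact centroids for speed; with K = 1 the
  centre approximates (not equals) the mean window.
- The eigengap heuristic for the spectral cluster count is a suggestion,
  not a substitute for choosing the granularity of interest.
- Disc packing by jitter fails above ~55% area coverage; denser tissues
  need smaller radii.
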