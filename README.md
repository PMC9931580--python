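# cytoniche

Spatial single-cell analysis of imaging mass cytometry (IMC) for tissue
microenvironments: marker-mask curation, pixel-majority cell phenotyping,
cell–cell interaction/avoidance permutation tests, cellular-neighbourhood
discovery, hybrid phenotype clustering and survival stratification of
spatial features — together with a synthetic-tissue generator that plants
ground truth for every stage.

It is written for analysts working with multiplexed tissue images
(IMC/CODEX-style: ~1 µm/pixel cores, one intensity channel per metal-tagged
antibody, an external cell-segmentation mask) who need the downstream
spatial statistics, not the segmenter.

## The methods

**Pixel-majority phenotyping.** Each lineage marker channel is turned into
a curated binary mask: 3×3 median filter → 1-D k-means quantization of
pixel intensities into 6 groups → selection of the brightest *L* groups as
foreground → removal of connected blobs below a minimum area → optional
local-mean adaptive-threshold refinement (sensitivity 0.4) and optional
percentile contrast enhancement. Each pixel *p* of cell *cᵢ* then carries a
presence vector E(p) = (p_{M₁}, …, p_{Mₙ}) ∈ {0,1}ⁿ over the n lineage-marker
masks, and the cell's majority vector is the pixel sum

&nbsp;&nbsp;&nbsp;&nbsp;M_{cᵢ}[k] = Σ_{j=1..N_{cᵢ}} p^j_{M_k}.

The cell is assigned the lineage whose defining-marker count is maximal
(ties broken by a configurable rank-priority hierarchy; all-zero vectors are
"Undefined"). Subphenotypes (microglia vs monocyte-derived macrophage by
P2Y12, M1-/M2-like by CD163, MPO⁺) come from mask-overlap positivity calls.
Per-cell expression is the mean raw pixel value per channel — no transform.

**Interaction/avoidance tests.** Cells within 6 µm (centroid distance) are
neighbours. For an ordered type pair (A, B), the statistic is the mean
number of B-neighbours per A-cell; the null is built by shuffling phenotype
labels over all cells of the image with positions fixed. One-tailed
p-values use (1 + #{null ≥ obs})/(n_perm + 1); a pair is called *interact*
or *avoid* at p < 0.01, read row-to-column.

**Cellular neighbourhoods (CNs).** Each cell's window is the type-frequency
vector of its N nearest cells; windows pooled over the discovery images are
clustered with mini-batch k-means (k-means++ init, fixed seed). Per-image
CN prevalence is normalized to 100%; cohorts are stratified by the z-score
(≥ 0 vs < 0) or median of a CN's patient-level prevalence, with duplicate
cores averaged per patient before any survival use.

**Hybrid phenotype clustering.** For very large cell sets: DBSCAN
(eps = 3, minPts = 30) isolates density-coherent clusters; the dominant
cluster is re-clustered by spectral clustering on a 1-in-10 subsample; a
5-NN classifier extends the labels to every cell.

**Cohort statistics.** Shapiro–Wilk-driven test selection (t/ANOVA+Tukey vs
Mann–Whitney/Kruskal–Wallis, with a large-sample override), Kaplan–Meier
curves with log-rank (Mantel–Cox) tests, Fisher exact tests, per-image cell
frequencies and densities with none / 1–5 / ≥6 cells·mm⁻² category calls.

## Worked example

```python
from cytoniche import (
    SyntheticTissueConfig, InteractionSpec, generate_image, generate_points,
    curate_maskset, build_cell_table, build_graph, permutation_test_all,
)

# phenotype a rendered synthetic core end to end
config = SyntheticTissueConfig.make(
    {"tumour": 0.5, "macrophage": 0.3, "tcell": 0.2},
    shape_px=(400, 400), n_cells=600,
)
stack, seg, truth = generate_image(config, seed=1, image_id="core01")
masks = curate_maskset(stack, config.panel(), seed=1)
cells = build_cell_table(stack, seg, masks, config.hierarchy())
accuracy = (cells["lineage"].to_numpy() == truth["type"].to_numpy()).mean()
print(f"cells: {len(cells)}, lineage accuracy vs planted truth: {accuracy:.3f}")

# permutation test on a planted-attraction point pattern
att = SyntheticTissueConfig.make(
    {"tumour": 0.6, "macrophage": 0.4}, n_cells=500,
    interactions=(InteractionSpec(("tumour", "macrophage"), "attraction", scale_um=4.0),),
)
points = generate_points(att, seed=2, image_id="core02")
graph = build_graph(points, radius_um=6.0)
results = permutation_test_all(graph, points["type"], n_perm=1000, seed=7)
row = results.set_index(["type_a", "type_b"]).loc[("tumour", "macrophage")]
print(
    f"tumour->macrophage: observed {row.observed:.3f} B-neighbours/A-cell vs null "
    f"{row.null_mean:.3f} +/- {row.null_sd:.3f}, p_interact={row.p_interact:.4g} -> {row.call}"
)
```

prints

```
cells: 600, lineage accuracy vs planted truth: 1.000
tumour->macrophage: observed 0.369 B-neighbours/A-cell vs null 0.218 +/- 0.019, p_interact=0.000999 -> interact
```

The first line says the full mask-curation + majority-vote chain recovered
every planted cell type on this core. The second line reads: tumour cells
averaged 0.369 macrophage neighbours within 6 µm, against 0.218 ± 0.019
under label shuffling — co-localization far beyond chance (the smallest
p-value 1,000 permutations can produce), so the pair is called an
interaction.

A thin CLI wraps the same stages
(`cytoniche simulate|validate|masks|phenotype|interactions|cn|survival`).

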