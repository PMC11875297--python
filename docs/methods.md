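# Methods

## Synthetic palate sections

A section is two mirror-image convex shelf polygons (~400×600 μm,
chamfered nasal corners, 200 μm midline gap), coordinates in μm with the
origin at the lower left and y increasing toward the nasal side. Each
shelf is cut by horizontal lines into three compartments:

| compartment | extent (default) | role |
|---|---|---|
| oral epithelium | lower 100 μm band | *Shh* source (0.08 tr/μm², zero elsewhere) |
| oral mesenchyme | band top → 35 % of shelf height | *Ptch1* elevated (0.05 vs 0.002 tr/μm² baseline) |
| nasal mesenchyme | remainder | baseline only |

Every other gene is an independent homogeneous Poisson process at a
log-normal baseline intensity (median ≈ 3×10⁻³ tr/μm², σ = 0.6 — tens of
transcripts per 6400 μm² ROI, matching a targeted in-situ panel's
per-gene density scale) times a per-condition rate ratio. The default
panel has 350 genes (two markers, two `mt-*` genes, a handful of named
palate genes, anonymous filler); 8 % of eligible genes carry an 8-fold
stage increase, 3 % an 8-fold decrease, 3 %/6 % knockout up/down — i.e.
|log₂ ratio| = 3, the scale of effects the ROI procedure is meant to
detect. Points are sampled by rejection from the bounding box, so the
compartment rate is exact. Cohorts derive per-condition sub-seeds from one
seed via `SeedSequence.spawn`; identical (config, seed) reproduce
byte-identical outputs.

The epithelial band is deliberately thicker than a real epithelium
(~100 μm vs a few cell diameters). The oronasal axis is fitted through
the *Shh*/*Ptch1* co-expression centroid, which sits at the band's
mesenchymal interface; the oral domain must still be deep enough to hold
an 80 μm ROI with placement margin. A band of ~one ROI side achieves that
while keeping marker confinement exact; the trade-off is geometric
schematism, not statistical distortion.

The high-definition simulation places non-overlapping random ellipses
(semi-axes 3–5 μm) in a 200×200 μm frame, draws per-nucleus per-gene
Poisson counts from one of two log-normal cell-type profiles
(≈ 0.3 transcripts/gene/nucleus), scatters them with an isotropic
Gaussian (σ = 2 μm) onto the 2 μm bin grid, and adds a uniform background
(2×10⁻⁴ tr/μm²/gene). The matching label mask is rasterized at 0.5 μm.
Generated per-cell counts are recorded, so bin→nucleus aggregation can be
checked exactly in the degenerate case (spread 0, background 0).

What the generator does **not** emulate: tissue morphology and cell
packing, segmentation errors, spatial correlation between genes,
overdispersion beyond Poisson, diffusion artifacts, batch effects.
Passing tests therefore demonstrate correctness and calibration of the
procedures under their own assumptions, not robustness to real-data
pathologies.

## Nucleus binning

A bin joins the nucleus whose region contains its center — at 2 μm
resolution fractional-overlap weighting would change little and would
break count integrality. Raster pixels are half-open boxes with the tie
rule that a point exactly on an edge belongs to the pixel to its lower
left; the rule is arbitrary but fixed, and matters because default bin
centers fall exactly on 0.5 μm pixel corners. No nucleus expansion is
applied (counts are mapped to nuclei, not to whole cells). Default cell
filters — area in [15, 400] μm², total UMI ≥ 10 — are nucleus-scale
plausibilities, exposed as configuration, not published cutoffs.
Mitochondrial removal matches gene names case-insensitively against the
`mt-` prefix (mouse nomenclature), hyphen included, so `Mtor` survives.

## Single-cell statistics

Normalization is library-size scaling to 10⁴ counts followed by
log₂(1+x). A regression-based variance-stabilizing normalization is the
common alternative; it is an external published algorithm and is
deliberately not reproduced — the analyses here depend on rank (AUC) and
two-group location statistics for which the simple transform suffices.

The marker ranking is the Mann–Whitney AUC (ties counted ½) of in-group
vs out-group expression, power = 2·|AUC − ½|, sorted by power with
lexicographic tie-breaks for determinism.

The hurdle DE test fits, per gene, group-wise MLEs closed-form:

* discrete part — binomial likelihood of detection (x > 0); LR statistic
  of group vs pooled proportions; dropped when detection is constant
  across all cells;
* continuous part — Gaussian likelihood of the positive values;
  LR = n·log(RSS₀/RSS₁); dropped unless both groups have a positive cell
  and at least three positives exist overall (with fewer, the saturated
  fit has no residual and the statistic is meaningless).

The summed statistic is referred to χ²(df), df = number of retained
components; a gene with no retained component (e.g. all-zero) reports
p = 1, LFC 0. LFC is the difference of group means of normalized values
including zeros. No covariates are fitted (none are defined for the
synthetic data). BH adjustment is the standard step-up procedure
(delegated to statsmodels; validated in tests against the definitional
min-over-tail formula). Calls use |LFC| > 1 and FDR < 0.01.

ORA is the hypergeometric upper tail of the hit overlap, set sizes taken
within the universe; the universe defaults to all genes in the analysed
matrix after mitochondrial removal. A term is reported only at P < 0.05
with ≥ 2 hit genes, so single-gene coincidences never surface.

## Domain geometry

Density maps bin transcripts on a 10 μm lattice shared across genes
(extent snapped from the full table) and divide by cell area; Gaussian
smoothing uses σ = 15 μm. The lattice resolves the epithelial band
without letting single-transcript noise dominate; at bandwidth 0 the map
is a raw histogram and conserves mass exactly (smoothing loses only edge
mass). The co-expression score is the geometric mean of the two
max-normalized maps — zero wherever either marker is absent — thresholded
at the 0.9 quantile of its nonzero values. The original procedure was
manual in a viewer GUI; quantile thresholding of a product score is the
deterministic formalization, and both the quantile and the bandwidth are
parameters.

The oronasal axis is the principal direction of the masked lattice cells
inside one shelf, through their centroid, with the oral side chosen as
the half-plane into which that centroid is displaced from the shelf
centroid. A straight line is the simplest reproducible stand-in for an
axis drawn by eye. The shelf polygon is split by the line; degenerate
halves (relative area ≤ 10⁻⁹) are rejected.

ROIs are axis-aligned 80 μm squares (area exactly 6400 μm²; the ±100 μm²
band is kept as a validation bound for user-supplied ROI tables, whose
shape the standard does not fix). Placement is seeded uniform rejection
inside each domain: fully contained, pairwise intersection area zero
(touching allowed), bounded attempts with the failing domain named.
ROI counting uses half-open squares (left/bottom edges in) so a transcript
on a shared edge is counted once.

## ROI differential expression

Each ROI is one replicate; the two shelves of a section are pooled, so a
scope has 6 (NP or OP) or 12 (whole) replicates per condition per
section. Fold changes are computed on raw densities with pseudocount
1/6400 μm⁻² — one transcript per standard ROI, the smallest physically
meaningful density — so zero densities never produce infinities while
real signals are barely perturbed. P-values come from the transformed
densities: the F-test is two-sided with the larger sample variance in the
numerator, at significance level 0.05 (the procedure's "critical value"
is read as an α level, since 0.05 is not an F quantile); Student's or
Welch's two-sided t-test follows. Two zero-variance groups give p = 1
when means agree and p = 0 otherwise. BH runs across genes separately per
contrast × scope (one volcano per panel). Classification defaults to the
**raw** p-value at P < 0.05 and |LFC| > 1 — the thresholds quoted with
the volcano figures — while the adjusted p is always reported and a
`classify_on` switch selects it instead; which of the two gated the
original printed DEG counts is ambiguous in the source description.
−log₁₀(p) is capped at 300 for p = 0.

## Problem sizes and calibration checks

The acceptance script and test suite use: 20 seeds × 100 genes for the
ROI-DGE null (type-I error within 3 binomial SE of 0.05); 5 seeds for
ROI-DGE power on the |log₂ ratio| = 3 genes (≥ 80 % classified "up");
200 genes at 50/50 cells for the hurdle null and 200 genes (20 true DE,
4-fold) at 100/100 cells for hurdle power (≥ 80 % pass FDR < 0.01,
|LFC| > 1, null false-positive fraction < 0.05); two seeded default
sections for geometry (partition area conservation to 10⁻⁶ relative,
≥ 95 % of the true epithelial band inside the recovered OP domain); and
two identical full runs for determinism. These sizes give stable
statistics at desk scale; all are parameters, not limits.

## Known limitations

* The compartments are horizontal slabs; curved epithelium, shelf
  elevation and anatomical axes are out of scope.
* The hurdle test's χ² reference is asymptotic; at very low detection
  rates per group it becomes conservative or undefined (components are
  dropped, reducing df).
* ROI placement is random within domains; the original ROIs were chosen
  manually, so spatial sampling bias of a human selector is not modelled.
* Real DEG lists from the deposited tissue data are not reproducible
  here; the synthetic cohort validates the procedures, not the biology.
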