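# Methods

## Scope and conventions

The package operates on single 2-D grayscale rasters with 8-bit intensity
convention ([0, 255]) and an explicit physical pixel size in µm (metadata in
files is never trusted over the argument). Pixel (0, 0) is top-left, x runs
rightward along columns, y downward along rows, and the center of pixel
(row i, col j) is (j + 0.5, i + 0.5). 16-bit inputs are rescaled by the
dtype maximum (not the image maximum) so constant-illumination series stay
comparable; RGB inputs are collapsed with the 0.299/0.587/0.114 luminance
weights (a channel-mean option exists). ROIs are simple polygons in pixel
coordinates; rasterization uses the pixel-center-in-polygon rule with
boundary centers included, and ROI areas are shoelace areas converted to
mm². DAB-positive signal is dark after grayscale conversion, so the default
threshold polarity is positive-below.

## The three readouts

**Densitometry.** The cutoff is Otsu's between-class-variance optimum
computed from ROI pixels only, so staining outside the evaluated region
cannot bias it; a fixed cutoff can be supplied instead. Comparators are
strict (`<` / `>`; ties go to background) for bit-exact reproducibility,
and the Otsu cutoff is therefore reported half an intensity level above the
optimal bin so the strict rule reproduces the canonical
lower-class-inclusive split on integer data. Percent area is
100·|positive ∧ ROI| / |ROI|.

**Cell density.** Connected components of the binarized foreground
(8-connectivity by default, so thin diagonal processes stay attached),
size-filtered in physical units (default minimum 20 µm², no maximum), are
counted when the pixel containing their centroid lies inside the ROI mask.
The centroid rule attributes a border-straddling cell to exactly one
region, so adjacent ROIs never double-count; for uniformly placed cells it
is unbiased. Density is count / ROI area (cells/mm²). No watershed
splitting of merged cells is attempted.

**Ramification index.** A_c is the segmented silhouette area (pixel count ×
pixel area), the automated surrogate for a manual outline. A_p is the area
of the convex hull of all four corners of every foreground pixel square
(SciPy Qhull; the test suite checks it against an independent
gift-wrapping + shoelace oracle). Because the hull contains the union of
the squares, A_p ≥ A_c always, RI = A_c/A_p ∈ (0, 1] is a provable bound,
and one-pixel-wide cells are not a degenerate case (their hull is a
rectangle). A hull over pixel *centers* can violate RI ≤ 1 for thin cells
and was rejected. Cells are selected by superimposing a rectangular grid
(default spacing: image width / 8, phase random per image from the pipeline
seed) and keeping every cell whose pixel set crosses a grid line — the
pixel [j, j+1) × [i, i+1) crosses the line x = c iff j ≤ c < j+1. Cells
touching the image border are excluded from morphometry because truncated
silhouettes bias RI upward; the exclusion count is reported.

## Group statistics

Per-animal values are summarized as arithmetic mean ± sample SD (n−1).
Grubbs' test is the classic single-pass two-sided single-outlier variant:
G = max|x−mean|/SD against
G_crit = ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) Student-t
quantile at n−2 df; at most one value per group is removed, and only for
the densitometric metric — morphology and density values are never
excluded. The omnibus test is the tie-corrected Kruskal–Wallis H with the
chi-square (k−1 df) upper tail; mid-ranks are used for ties throughout.
Post hoc comparisons are Dunn's z of each group against the control,
z = Δmeanrank / √((N(N+1)/12 − Σ(t³−t)/(12(N−1)))·(1/n_g + 1/n_ctrl)),
two-sided normal p, Bonferroni-multiplied by the number of comparisons
(an all-pairs mode exists but the cohort designs compare against control).
Symbols: `***` p ≤ 0.001, `**` p ≤ 0.01, `*` p ≤ 0.05, else `n.s.`.

Two properties of this pipeline are worth knowing. First, the chi-square
approximation to the exact permutation p is accurate in the decision-
relevant tail (within 0.03 of the exhaustive permutation value for 3×3
designs wherever p ≤ 0.2) but deviates up to ~0.10 near H = 0, where the
discrete null mass dominates; standard software shares this behavior.
Second, with small groups a rank test compresses effect sizes: four
perfectly ordered groups of n = 5 give the group adjacent to control a
mean-rank gap of 5 and z ≈ 1.34, which can never reach significance — the
reason early-timepoint comparisons in this design read n.s. even when the
mean shift looks large.

## The synthetic generator

A model cell is a soma disk plus processes drawn as discrete random walks
(unit-µm steps, heading perturbed by Normal(0, wiggle) per step, attached
to the soma boundary at quasi-uniform angles, thickness applied by disk
dilation). Masks are 4-connected by construction. A single `retraction`
knob r ∈ [0, 1] morphs resting into activated morphology:

| parameter | default | unit | meaning |
|---|---|---|---|
| soma_radius_um | 4.0 | µm | soma radius, grows as ×(1+r) |
| n_processes | 6 | — | process count, shrinks as ×(1−0.99r) |
| process_length_um | 25.0 | µm | walk length, shrinks as ×(1−r) |
| process_thickness_um | 1.5 | µm | dilation diameter of process paths |
| wiggle | 0.25 | rad/step | SD of the per-step heading change |
| mu_fg / mu_bg / sigma | 70 / 210 / 12 | intensity | Gaussian stain model |

The per-cell process and step counts use stochastic rounding
(floor + Bernoulli of the fraction) so the population mean RI is a
continuous, monotone function of r; with hard rounding it jumps where the
integer count flips, leaving target means unreachable. `calibrate_retraction`
inverts the map by bisection with common random numbers (the same per-cell
seeds at every evaluation, making the objective deterministic); the default
tolerance is ±0.02 in mean RI, tightened to ±0.0075 with 40 probe cells
inside cohort generation. Reachable mean RIs with the default family span
roughly 0.33–0.95; cohort generation truncates per-animal Normal draws to
that achievable interval (clipping to the nearest endpoint), consistent
with truncating all per-animal draws to valid ranges.

Scenes place cells by dart throwing with a minimum centroid separation
(default: soma radius + process length, i.e. 2×(soma+length)×0.5 = 29 µm)
*and* mask-level rejection: a freshly drawn cell whose pixels would touch
an existing cell's 8-neighbourhood is redrawn at a new position. Every
emitted cell is therefore a distinct connected component and
connected-component counting has unambiguous ground truth — a deliberate
simplification: confluent microgliosis plaques, uneven illumination,
section artifacts and color are not emulated, so passing recovery tests
demonstrates correctness of the measurement chain, not robustness to
heavily fused late-timepoint white-matter fields (where densitometry, not
counting, is the appropriate readout anyway). Foreground/background
intensities are iid Gaussian draws clipped to [0, 255]; with sigma = 0 the
scene is exactly separable at the midpoint cutoff, which several tests
exploit.

Cohorts draw per-animal targets Normal(group target, between-animal SD),
truncated to valid ranges; a group is sized either by a density target
(count = round(density × ROI area)) or by a percent-area target (count
estimated from the mean probed cell area). Reproducibility: one root seed;
the stream for group g, animal a is `SeedSequence([seed, g, a])`, and
analysis streams use a separate tag, so generation is order-independent
and bit-identical across reruns.

## Recovery experiments and problem sizes

The validation experiments generate a five-animal cohort calibrated to a
published group value, run the full pipeline on the rendered images, and
compare the recovered cohort mean with what was seeded. Scenes are 700×700
px at 1.0 µm/px with a 620×620 px square ROI (≈0.384 mm²); RI cohorts use a
control-like 90 cells/mm² (≈35 cells/scene, of which the default grid
samples most), between-animal RI SD 0.04. Density cohorts are seeded at the
group value with zero between-animal SD so the check isolates measurement
recovery rather than the luck of five Normal draws. Densitometry cohorts
draw per-animal percent-area targets with SD 0.96 and are evaluated with
ROI-restricted Otsu under the default noise model. These sizes keep a full
recovery run in seconds on one CPU while leaving ≥50 analyzed cells per
cohort; they were chosen as the smallest design that still mirrors the
n = 5 group structure.

Because the cohort mean of five Normal(target, 0.04) draws itself has an SE
of ≈0.018, a recovered cohort mean can sit ±0.04 from the group target in
an unlucky cohort with no measurement error at all; the recovery tables
therefore report the seeded per-animal draws alongside, and the
recovered-vs-seeded gap is the measurement-quality number (typically
< 0.005 in RI, < 1% in density, < 0.1 percentage points in percent area).

## Known limitations

- Grid selection favors spatially larger (more ramified, lower-RI) cells;
  with the default spacing most interior cells cross a line, so the bias is
  small (≲0.01 in mean RI) but not zero.
- The generator's cells never overlap, so precision/recall of detection is
  1 on its output; real microgliosis fields will fuse components.
- Otsu assumes a bimodal ROI histogram; it is exact down to ≈2% positive
  area under the default stain model but is undefined on constant regions
  (a degenerate-histogram error) and unreliable when foreground and
  background distributions overlap heavily.
- The stats stage assumes one value per animal; nested (per-cell) variance
  is deliberately collapsed to the animal mean before testing, as in the
  cohort designs it mirrors.
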