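# Methods

`slicequant` implements the quantification chain used to evaluate thin-cut
tissue slice cultures (tumor slice cultures, TSC, and organotypic brain slice
cultures, OBSC) after proton irradiation: DNA-damage readout via γH2AX foci,
slice morphology from stained sections, plate-based cytotoxicity and
viability arithmetic, the statistics that validate and compare those
readouts, and the dosimetric QA of the irradiation field. Every stage can be
exercised on synthetic inputs with exact ground truth; this note records the
models, the parameters that matter, and the design decisions taken where the
procedure was genuinely open.

## Nucleus segmentation and γH2AX foci counting

**Model.** Nuclei are segmented from the DAPI channel by automated
thresholding — Otsu on the Gaussian-blurred channel by default, an explicit
threshold optionally — followed by 8-connected labeling. Merged blobs are
optionally separated by a distance-transform watershed. Foci are counted per
nucleus as local intensity maxima of the Gaussian-blurred γH2AX channel: a
maximum is a pixel, or a connected plateau of equal-valued pixels counted
once, strictly greater than every pixel adjacent to it (8-neighborhood), and
it must clear a *prominence* floor — its height above the within-nucleus
background (the within-nucleus minimum of the blurred channel) must exceed
`maxima_prominence × (nucleus max − nucleus background)`. The whole chain is
deterministic; there is no randomness anywhere in the analysis path.

**Parameters.**

| parameter | default | units | rationale |
|---|---|---|---|
| `pixel_size` | user-supplied | µm/px | all areas are converted to µm² via `pixel_size²` before filtering |
| `blur_sigma` | 1.5 | px | suppresses single-pixel noise without merging adjacent foci at 40× sampling |
| `area_min_um2` | 65 | µm² | inclusion requires area strictly *above* the cutoff; 65.0 exactly is excluded |
| `maxima_prominence` | 0.2 | relative | without a floor, flat noise yields unbounded maxima |
| `split_depth_px` | 2.0 | px | minimum watershed-marker suppression depth (see below) |

**Watershed marker extraction.** Markers are the regional maxima of the
grayscale reconstruction of `(distance − h)` under `distance`, computed per
connected blob with `h = max(split_depth_px, 0.2 × blob max distance)`. Two
facts motivate this form. First, the Euclidean distance transform of a
digitised, noisy-edged ellipse carries ridge saddles of ~2–3 px that must
not split a single nucleus, while a genuinely merged pair (centers at 0.8×
the radius sum) has a saddle roughly 0.28× the blob's maximum distance —
the relative term separates the regimes at any magnification. Second,
thresholding the h-maxima *residue* (the common shortcut) disconnects
equal-height twin peaks at any saddle depth, manufacturing two markers for
one symmetric nucleus; taking regional maxima of the reconstruction keeps
such peaks in one connected plateau.

**Inclusion filtering.** The manual verification step of the original
workflow is replaced by an explicit exclusion-list file, for reproducibility
and headless operation. Exclusion reasons are evaluated in the order
listed-excluded → below-area → border; border-touching nuclei are dropped by
default because their area estimate is incomplete. Excluded nuclei carry
`foci_count = 0` (not evaluated), never a partial count.

**cfoci.** Counts are corrected for nuclear cross-section:
`cfoci_i = foci_i × (group mean area / area_i)`, with the mean taken over
the included nuclei of the same treatment group. A nucleus at exactly the
group mean keeps its raw count, and
`Σ cfoci_i·area_i / mean_area = Σ foci_i` holds algebraically.

**Binary positivity.** For tissue where discrete foci cannot be resolved
(adult brain slices), a nucleus is scored positive when its mean γH2AX
signal exceeds `positivity_threshold ×` the slide background (median signal
outside all nuclei). The default threshold of 2 suits images whose nuclei
are dark unless positive; if negative nuclei carry a dim pan-nuclear
baseline, the threshold must be placed between that baseline and the bright
level.

**Known limitation.** The relative prominence rule is anchored to the
within-nucleus intensity span. In a nucleus containing *no* focus, the span
collapses to the noise range and every noise maximum clears the relative
floor, so spot-free nuclei are over-counted under noise. An absolute noise
floor would fix this but would introduce an intensity-calibration parameter;
the relative rule is kept as the defined behavior, and the recovery
guarantees below are stated for nuclei carrying at least one focus.

## Stained-section morphology

RGB brightfield images are converted to optical density,
`OD = −log10((I + ε)/white)`, and unmixed by least squares onto unit stain
absorption vectors (Ruifrok–Johnston hematoxylin/eosin and
hematoxylin/DAB triplets by default, overridable for scanner variation);
negative concentrations are clipped at zero. The tissue mask is total OD
above a background threshold (default 0.10). Necrosis on H&E is defined as
eosin-dominant tissue that has lost its hematoxylin-stained nuclei: tissue
pixels with hematoxylin concentration < 0.45 and eosin > 0.45, cleaned by
morphological opening and closing (disk radius 2). DAB- and DAPI-positive
areas use a single concentration (or fluorescence) threshold over the tissue
mask. All outputs are fractions of tissue pixels; an image without tissue is
flagged undefined rather than reported as zero.

Depth profiles order slices from the skin side; the depth of slice *i* is
`i × 500 µm` with the origin at the first slice (the cutting protocol fixes
the thickness; the origin is this package's convention).

## Plate-assay arithmetic

LDH cytotoxicity: the blank-corrected signal is `A(490) − A(680)`; with the
terminal detergent-lysis reading, `total = lysis + Σ daily`, the daily
cell-death fraction is `daily_i / total`, and survival is 1 − cumulative
death. Negative blank-corrected signals are retained with a warning rather
than floored, so the identity `Σ deaths + final survival = 1` holds to
machine precision; the repaired series (clip to [0, 1], then a running
minimum, applied only at the final fraction stage) is reported alongside the
raw one. Resazurin viability:
`corrected = A_s(571) − A_s(601) − (A_m(571) − A_m(601))`, algebraic
throughout. Time courses are normalised to day 1 in culture to absorb
slice-size variation; a zero day-1 value makes the series undefined and
raises. Day indexing is 1-based to match the summation convention of the
cumulative-death formula.

## Statistics

**Bland–Altman.** Differences `d = a − b`; bias = mean(d); SD with the n−1
denominator; 95% limits of agreement `bias ∓ 1.96·SD`. Used to compare two
human counters, or counter versus algorithm.

**Pearson matrix.** Pairwise Pearson R over the morphology columns with
two-sided p from the exact t distribution (n−2 df), listwise deletion, and
zero-variance columns flagged as undefined rather than silently skipped.

**Slice-clustered permutation test.** Treatment comparisons on per-nucleus
readouts must respect that nuclei are nested in slices; slices, not nuclei,
are the exchangeable units. Instead of a linear mixed-effects model, the
package uses a permutation test: the statistic is the difference of group
means of *slice means* (each slice weighs equally regardless of its nucleus
count), group labels are permuted across whole slices respecting group
sizes, and the two-sided p-value uses the add-one correction
`(1 + #{|T*| ≥ |T|}) / (n_perm + 1)` so p is never zero. The permutation
test answers the same question as the mixed model under weaker assumptions
(exchangeability of slices under the null) at the cost of not estimating
variance components; this trade was made deliberately to keep the inference
procedure fully defined within the package. Calibration measured by
simulation: empirical type-I error 0.037–0.059 across seeds at nominal 0.05
(1000 null replicates, 199 permutations each), power ≈ 1.0 at an effect of
5× the within-slice SD with 8 vs 7 slices.

## Film-dose QA

Net optical density is converted to dose by monotone piecewise-linear
interpolation through user-supplied calibration nodes (nodes map exactly;
out-of-range OD is clamped with a warning, never extrapolated). Homogeneity
over a region of interest is `H = 100 × D_low / D_high`, where `D_low` and
`D_high` are the 2nd and 98th percentile doses within the ROI — the
percentile clip makes the metric robust to dust and film artifacts, and H is
invariant to global dose scaling. The acceptance criterion for slice
irradiation plates is H ≥ 95%. The specific percentile-ratio form is this
package's definition; the criterion it serves states a threshold but no
metric.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes, with exact truth:

- **Fluorescence scenes** — nuclei as filled ellipses (aspect 0.6–1.0,
  lognormal areas, median 120 µm², σ 0.25 at 0.25 µm/px) with
  Gaussian-blurred edges; foci as additive Gaussian spots (σ 2 px, amplitude
  1.0) placed inside an eroded nucleus mask with a pairwise minimum
  separation (greedy dart-throwing over shuffled interior pixels, so failure
  genuinely means the requested density is unsatisfiable); apoptotic/mitotic
  nuclei rendered pan-bright with no resolvable spots — these are the cells
  the exclusion list exists for. Noise is Gaussian with
  intensity-proportional SD (default 2%), a shot-noise approximation chosen
  because the thresholding and maxima logic under test are insensitive to
  the exact noise law. Touching pairs (centers at 0.8× the radius sum) are
  generated on request to stress the splitter.
- **Stained sections** — two-class layouts mixed through Beer–Lambert
  optical densities with Gaussian OD noise (default SD 0.02). Viable tissue
  is hematoxylin-dominant; necrosis eosin-dominant ("light pink");
  DAB-positive tissue adds a strong DAB component over the counterstain.
- **LDH kinetics** — daily lysed fractions (summing to ≤ 1) scaled to
  absorbance over a shared 490/680 baseline, plus a terminal-lysis reading
  proportional to the residual pool.
- **Paired counters** — additive per-arm error laws, rounded to non-negative
  integers.
- **Depth profiles** — a Gaussian copula over (depth, necrotic, CD44, DAPI)
  whose default targets are the six pairwise correlations measured on the
  tumor slices (−0.88, 0.67, 0.83, −0.61, −0.71, 0.76). The latent
  correlation is pre-adjusted by `ρ_z = 2·sin(πρ/6)` — the exact inversion
  of the Gaussian-copula Pearson relation for uniform marginals — and
  fractions are affine maps of the uniforms (necrotic 0.20–0.80, CD44
  0.10–0.70, DAPI 0.30–0.90), which preserves Pearson correlation, so the
  *output* correlations converge to the targets. Depth's latent coordinate
  is the deterministic normal-score grid of the ordered slices; the other
  variables are drawn conditionally. If a valid target matrix maps slightly
  outside the PSD cone under the arcsine adjustment, the latent matrix is
  repaired by eigenvalue clipping; a non-PSD target itself is an error.

What the scenes do *not* model: photorealistic chromatin texture, 3-D
z-stacks, out-of-focus light, stain spatial inhomogeneity, scanner gamma,
slide-wide illumination gradients, or proton depth-dose physics. Passing
tests on these scenes demonstrates that the measurement chain is correct and
calibrated on data whose truth is known — not that the thresholds transfer
to any particular microscope; the stain vectors and thresholds are exposed
as configuration for that reason.

## Problem sizes used in the checks

The verification suite runs 50 random scenes (128–192 px) against an
exhaustive brute-force maxima enumeration plus one 512² scene, 20
recovery scenes at 384², 100 seeded depth profiles of 500 slices per
correlation target, 1000 null and 200 alternative permutation replicates,
and 256² stain scenes; these sizes give stable statistics (binomial SE
≈ 0.7% on the type-I estimate) while keeping the whole suite fast enough to
run routinely.
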