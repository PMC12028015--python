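# Methods

This note documents the models, parameter choices and numerical
decisions behind `cordquant`, and what the synthetic validation does
and does not establish about real histological data.

## Coordinate conventions

All analysis happens in continuous µm coordinates with the origin at
the top-left corner of the frame and y increasing ventrally. Pixel
(i, j) of a raster with pixel size s covers
[j·s, (j+1)·s) × [i·s, (i+1)·s); its centre is ((j+0.5)s, (i+0.5)s).
Centroids reported from rasters use the centre convention, so a
detection from a segmented raster and the µm ground truth agree without
half-pixel offsets. All text outputs print µm with 3 decimals.

## Toy atlas

`build_toy_atlas` constructs a schematic grey-matter map: a central
column with mirrored dorsal and ventral horn ellipses (all ellipse
centres lie within the column half-width, which guarantees that any
horizontal cut of the union is a single connected polygon), partitioned
into `n_laminae` equal-height bands L1 (dorsal) … Ln (ventral), with
five small circular nuclei (D, ICI, IMM, IML, LDCom) centred on band
boundaries so subtraction notches the neighbouring laminae without
creating holes. The construction is purely procedural and
deterministic. It reproduces the *topology* the analysis needs —
simple, non-overlapping, uniquely named regions covering the grey
matter, with a dorsal→ventral ordering — not the anatomy of a real
thoracic section; region areas and adjacencies are not calibrated to
any atlas plate.

## Section generator

For each region r the neuron count is Poisson with mean
`density(r) · area(r) · survival(distance, r)`. Neuron positions are
uniform within the region (rejection sampling), soma radii are
truncated-normal (mean 5 µm, sd 0.8 µm, floor 3.5 µm), so soma areas
(~38–100 µm²) sit safely above the 25 µm² particle filter — the
defaults exist to make that filter meaningful, since real soma-size
distributions for this preparation are not part of the model.

Rendering paints each soma as a hard disc in the neuronal channel with
a concentric nuclear disc at 0.75× the radius, multiplies intensities
by a per-section log-normal staining gain (sd 0.2 by default, modelling
the large section-to-section staining variability that motivates
per-image threshold choices), blurs with a Gaussian PSF (default 1 px;
no measured PSF is modelled) and adds Gaussian read noise. Artifacts
are discs bright in the neuronal channel only — no nuclear
colocalisation — placed uniformly over the whole frame at a default 5
per mm²; this encodes the observation that false detections stem from
autofluorescence and debris lacking a DAPI-positive nucleus.

The default survival curve is piecewise linear through
(0.6 mm, 0.023), (0.8, 0.20), (1.0, 0.40), (1.2, 0.40), clamped outside
that range; `distance = None` means an uninjured control (survival 1).
The same gradient applies to every region by default. A per-region
scaling hook (`default_survival_curve(region_scale=...)`) exists for
simulating the observed heterogeneity (dorsal laminae spared,
intermediate grey hit hardest), but it is off by default: the
whole-section gradient is the quantity the recovery tests measure, and
any non-uniform scaling changes the density-weighted whole-section
survival away from the nominal curve unless the scales are tuned to
cancel — a calibration with no independent basis.

Reproducibility: one integer seed expands through
`numpy.random.SeedSequence` into independent child streams per stage
(counts, positions, radii, artifacts, gain, noise) and per section, so
identical configuration yields bit-identical images and truth, and
stages can be re-run independently.

The probability-map generator emits 1 on true soma pixels and 0
elsewhere; a miscalibration parameter m > 0 replaces these by
1 − |N(0, m)| and |N(0, m)| respectively, clipped to [0, 1]. This is a
stand-in for a trained per-pixel classifier: it reproduces the output
*contract* (a [0,1] raster in which true somas are high-probability
particles and artifacts are background), not the failure modes of any
particular network.

Simulated observers detect each true neuron independently with
probability `sensitivity`, jitter reported positions isotropically, and
add uniform false positives inside the grey outline. Independence
across observers is what makes agreement classes Binomial(K, p); real
raters are correlated (they miss the same faint somas), so the binomial
check validates the matching machinery, not human behaviour.

## Detection

Thresholds: Otsu, triangle, isodata and mean via scikit-image, a fixed
user value, or `auto`, which evaluates all histogram methods and keeps
the cut maximising foreground/background mean contrast. `auto` is a
deliberate, reproducible replacement for the per-image manual algorithm
choice that semi-automated macros require; a constant image returns its
maximum (nothing segmented) as the documented degenerate fallback.

Colocalisation follows a component rule rather than a pixel AND: a
soma component is kept if it intersects the thresholded nuclear mask
dilated by 1 px. The exact rule used by lab macros is not standardised;
the component rule was chosen because a pixel-wise AND fragments somas
whose nuclear signal is off-centre. The area filter is strict
(area > 25 µm², so an exactly-25 µm² particle is discarded), matching
the wording "particles above 25 µm²". Components use 8-connectivity;
the optional watershed splits touching somas from smoothed
distance-transform maxima with a minimum seed separation (default 3 px)
exposed because arbitrary splitting is a known failure mode of macro
pipelines.

## Consensus matching

Candidate links (pairs of points from different sources within the
radius) are processed in order of increasing distance, merging clusters
under a union-find when the sources are disjoint and all cross-pair
distances stay within the radius. Ties are broken by source index then
coordinates, so the partition does not depend on input-set order.
Default radius 10 µm ≈ one soma radius; it is recorded in the output.
The exhaustive oracle (`cordquant._bruteforce`) enumerates set
partitions within connected components of the radius graph and
minimises (object count, total within-object pairwise distance); the
greedy matcher attains this optimum on all tested instances where
clusters are separated by more than the radius, which is the regime the
radius is chosen for.

RNN = Σ k/K was chosen among the possible "weighted consensus"
readings because it makes the reference count exactly the mean of the
per-analyst counts — an interpretable, analyst-symmetric property that
the test suite asserts to 1e-9.

## Agreement statistics

Bland–Altman limits are `mean(d) ± 1.96 · sd(d)` with the sample
(n−1) standard deviation. Plots of this kind are sometimes labelled
"95 % confidence intervals"; what is computed (and what such plots
actually show) are limits of agreement, and the code names them so.
Repeatability models regress the *absolute* difference between repeated
counts (the signed difference belongs to Bland–Altman) on candidate
predictors via OLS; candidates are ranked by adjusted R² and every
nested pair is compared by F-test. Rank-deficient designs raise an
error naming removable collinear columns. p-values are reported at
machine precision with no multiplicity correction; `quantify` reports
the number of tests performed instead.

## Thin-plate-spline registration

The standard TPS system is solved directly (dense, ≤ ~56 unknowns for
the practical 11–53 landmark range):

    [K + λI  P] [w]   [v]        K_ij = U(‖x_i − x_j‖),  U(r) = r² log r²
    [Pᵀ      0] [a] = [0]        P = [1 x y]

with U(0) = 0. λ = 0 interpolates every landmark exactly (residuals
< 1e-6 µm across the test suites); λ > 0 trades fidelity for
smoothness, and the landmark residual sum is non-decreasing in λ.
Distances stay in µm with no rescaling — for these landmark counts and
frame sizes the system conditioning is unproblematic, and rescaling
would change λ's units. Collinear or duplicated source landmarks raise
errors naming the offending indices.

The default direction maps the atlas (moving) onto the section, so
detections are never deformed; the inverse direction is exposed for
workflows that warp the section into atlas space instead. Region
polygons are densified (default edges ≤ 10–25 µm) before vertex
mapping so curved warps are preserved; a warped ring that
self-intersects is flagged `simple=False` with a warning, and
downstream counts from flagged regions should be treated as
low-confidence. Region assignment tests polygons in atlas order and
keeps the first hit, which resolves shared-boundary points
deterministically — boundary assignment has no principled rule when
the atlas comes from a different individual.

## Quantification

The control reference is the per-region *median* across control
sections (medians are used throughout because staining artifacts
produce heavy-tailed counts); at least one control section is required
and fewer than three triggers a warning. Regions with zero control
median get NaN survival and are listed as undefined rather than
silently dropped; excluded sections are missing rows, never zeros.
Kruskal–Wallis uses the tie-corrected H (scipy) with a chi-square p on
g−1 df; a permutation alternative reuses an independent tie-corrected H
implementation and the add-one estimator over shuffled pooled ranks.
With all observations identical, H is defined as 0 with p = 1. At
group sizes around 15 the chi-square and permutation p-values agree to
about ±0.02 — the residual is the chi-square approximation error, an
order of magnitude above the Monte-Carlo noise of 10⁵ permutations, so
the validation asserts that combined tolerance.

## Validation scope: what the synthetic harness shows

The cohort-recovery check (100 simulated cohorts of 3 control + 8
injured sections at 2 µm/px, ~1.6 mm² grey matter, ~450 neurons per
control section; sizes chosen to keep the Poisson error per distance
well under the 5-percentage-point acceptance band) establishes that
simulation, detection, registration and quantification compose without
bias beyond ~2 percentage points. The residual positive bias comes
from touching-soma merging, which is density-dependent and therefore
slightly stronger in control sections, inflating survival ratios — the
same direction the effect would take in real tissue.

What passing does **not** show: robustness to real tissue texture,
uneven illumination or staining gradients within a section (the gain
model is global per section); correlated rater behaviour; registration
quality under real morphological deformation, where landmark placement
is subjective; or 3-D effects, since the generator models projected 2-D
sections only.

## Known limitations

- The generator has no white matter, no tissue texture, and no
  within-section staining gradients.
- The matcher is greedy; its optimality certificate covers the
  well-separated regime, not dense clutter where cluster spacing
  approaches the linking radius.
- No probabilistic rater model (e.g. Dawid–Skene) and no
  segmentation-mask IoU matching; objects are points.
- No mixed-effects repeatability models or intraclass correlation
  coefficients.
- No intensity-based automatic registration; landmarks are the input.
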