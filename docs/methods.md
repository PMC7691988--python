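# Methods

## Image model

A simulated cell fills its micropattern exactly (the experimental
design this emulates selects fully spread single cells; partial
spreading is out of scope). The pattern is a filled axis-aligned
rectangle of the requested area and aspect ratio, centred in a frame
sized to the pattern plus a background margin (default 16 px). Side
lengths are rounded to whole pixels independently; at the default
pixel size of 0.4 µm/px (a 20× objective regime) this keeps the mask
area within ~2% of the request. The nucleus is an ellipse concentric
with the pattern, same orientation, with area equal to
`nucleus_area_fraction` × cell area (default 0.25) — real nuclear
geometry is more variable, but no stage of the analysis depends on the
nuclear shape beyond containment.

Expected channel intensities (photons/pixel): `pattern` and `actin`
are uniform fills of the pattern at their channel brightness; `dna` is
nonzero only in the nucleus; `marker` is brightness·ρ in the nucleus
and brightness·1 in the cytoplasm, where ρ is the
nuclear:cytoplasmic partition coefficient (ρ = 1 is a freely diffusing
control). Default brightnesses (150–300 photons/px) put the shot-noise
coefficient of variation at 6–8% per pixel, a realistic regime for
immunofluorescence at moderate exposure.

Noise follows the standard camera model: a Poisson draw on the
expected photon image, then additive Gaussian read noise (default
σ = 2 photons). Optional Gaussian blur (in µm) is applied to the
expected image before noise; the default is no blur, since
20×-regime images are treated as already depth-integrated and pixel
discretisation provides comparable smoothing. A `zstack` mode renders
5 planes with weights (0.1, 0.2, 0.4, 0.2, 0.1) that sum to 1, so the
z-summed stack reproduces the single-plane expectation — this is what
the sum-projection path is validated against, not a physical PSF.

When a second marker channel is requested (`coloc_mixing` set), both
marker channels are modulated by smooth multiplicative texture fields
(Gaussian-filtered white noise, correlation length 1.2 µm, relative
strength 0.4, mean ~1). The second channel's texture is a convex
mixture: fraction `coloc_mixing` of the first channel's field plus
(1 − mixing) of an independent field, so mixing 0 gives statistically
independent signals and mixing 1 an affine copy. The strength was set
from the signal budget — texture variance (0.4·200 photons)² against
shot + read variance (≈ 204 photons²) bounds the attainable Pearson
at ≈ 0.97 — not tuned after the fact. Texture is only rendered in
colocalisation scenarios so that plain partition experiments keep
exactly flat compartment intensities (and their exact-equality
properties). The compartment means of the texture fluctuate by a few
percent per cell (the smoothing correlates pixels), which adds
realistic cell-to-cell N/C-ratio scatter without biasing cohort
medians.

What the simulator does **not** emulate: physical optics (real PSFs),
3-D nuclear shape, stress fibres or other actin structure, multi-cell
scenes, uneven illumination, and autofluorescence backgrounds. Passing
tests therefore demonstrate correctness of the measurement chain under
a controlled, well-specified image model — not robustness to every
artefact of real microscopy.

## Segmentation

Thresholds minimise the Li–Lee cross entropy
η(t) = −(S_b·ln µ_b + S_f·ln µ_f) over the below/above partition at t
(S: class intensity sums, µ: class means; the data-dependent part of
the cross entropy between the image and its two-level reconstruction).
The production path runs Li's iterative fixed point
t ← (µ_b − µ_f)/(ln µ_b − ln µ_f) from the global mean and then
descends the exact discrete objective over neighbouring candidate
splits: the fixed point solves the continuous stationarity condition
and, on images with overlapping classes, can land one intensity gap
away from the discrete argmin. Candidate thresholds are midpoints
between consecutive distinct intensities, making the exhaustive-scan
oracle exact for any bit depth; because η is constant inside an empty
intensity gap, agreement between the two routes is defined on the
induced binarisation, not the float threshold. Intensities are shifted
to a strictly positive scale (minimum + 10⁻⁹ × range) before taking
logarithms; thresholds are reported on the original scale. The
threshold scales with the image (t(c·I) = c·t(I)), so all masks are
intensity-scale invariant.

Nucleus: threshold the DNA channel, fill holes, keep the largest
connected component; components touching the image border are
rejected (only fully imaged single cells are analysed, and rejections
are logged, never silent). Cell body: same recipe on the actin
channel (marker channel as fallback) with a radius-2 px morphological
closing before hole filling to bridge dim cytoplasm. If a supplied
nucleus mask is not contained in the cell mask, containment is
repaired by union and logged. Compartments: nucleus clipped to the
cell, cytoplasm = cell ∖ nucleus; a nucleus covering ≥ 98% of the
cell raises (no usable cytoplasm). Aspect ratio is the major/minor
axis ratio of the moment-equivalent ellipse (rotation invariant; for
a filled rectangle it equals the side ratio); an axis-aligned
bounding-box variant is available behind a flag.

## Quantification

Background defaults to the median intensity outside the cell mask per
channel, clipped at zero (read noise is zero-mean, so a negative
median means "no background" rather than a negative offset); a
constant override is available. Intensities are background-subtracted
and clipped at zero before compartment means; 20×-regime images are
treated as depth-integrated, and the z-sum projection is applied only
when a stack is supplied. Whether to subtract background before
ratioing is genuinely open in this kind of analysis; both modes are
exposed and the outside-median default is documented here. Cohort
summaries use medians. Pearson colocalisation is computed per
compartment on raw intensities of one characteristic plane by default
(the coefficient is invariant to the constant offset subtraction
would remove); zero-variance compartments yield NaN flagged as
undefined, never 0.

## FRAP

The generator solves the two-pool exchange model
df_n/dt = k_in·f_c − k_out·f_n (and its mirror) from the pre-bleach
steady state f_n/f_c = k_in/k_out, multiplies the bleached
compartment by the residual at t = 0, and conserves total
fluorescence afterwards (acquisition photobleaching is ignored —
pool intensities are concentration-proportional). The post-bleach
nuclear signal is exactly I_∞ ∓ A·e^(−kt) with k = k_in + k_out, which
is why the fitting module uses a single exponential: it is the minimal
model consistent with two-pool exchange, and the fitted rate is the
sum of the transport rates. Defaults (duration 120 s, dt 0.5 s,
5 s pre-bleach) make rates on the 0.01–0.5 s⁻¹ grid identifiable;
they are package choices, as no reference rate values exist to match.

Fits run bounded least squares (k ≥ 0, A ≥ 0) on the post-bleach
window (the bleach frame itself excluded), initialised from a
log-linearised estimate with a 3-point multi-start on k (×0.3, ×1,
×3) against local minima on noisy traces. A fitted amplitude below
10⁻³ of the signal span is flagged `flat` (rate not interpretable);
non-convergence of all starts raises with per-start diagnostics.

## Statistics

The decision tree: with min n ≥ 30 per group, a two-sample t-test
(2 groups) or one-way ANOVA with Tukey–Kramer posthoc (> 2); with
min n < 30, an Anderson–Darling normality screen per group at α
(default 0.05 — the screening level is a package choice), any
rejection switching to Wilcoxon rank-sum (2 groups) or Kruskal–Wallis
with Dunn posthoc, Šidák-adjusted (> 2); whenever an ANOVA would run,
Levene's test first (Brown–Forsythe median-centred variant for
robustness, toggleable to mean-centred), with unequal variances
diverting to Kruskal–Wallis. Dunn's z statistics are computed from
pooled-rank sums with tie correction; for two groups they reduce to
the rank-sum normal approximation, which the tests use as a
cross-check. The Student t-test is pooled-variance by default with a
Welch flag. Cells from all repeats are pooled before testing and the
report flags that no hierarchical (replicate-level) correction is
applied — a deliberate mirror of common practice, not an endorsement.
Simulation places the procedure's type-I error within [0.03, 0.07] at
α = 0.05 under both normal and lognormal nulls.

## Problem sizes and determinism

Validation cohorts use 100–200 cells per condition and null
calibrations 5000 replicates; at the default frame sizes one cell
simulates and measures in ~15 ms, so the full suite and the
acceptance script each run in well under a minute of compute per
stage. All randomness flows from explicit integer seeds; cohorts
spawn per-cell seeds from one master `numpy.random.SeedSequence`, so
identical configurations reproduce outputs bit for bit.

## Known limitations

Single-cell scenes only (multi-object images are rejected, not
split); no Manders/Costes colocalisation; no diffusion-limited FRAP
models or bleach-spot geometry corrections; no mixed-effects handling
of replicate structure; the simulator's idealised geometry means
segmentation accuracy bounds measured here are optimistic for real
data.
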