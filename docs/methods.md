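# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and the
known limitations.

## 3D nuclear segmentation

Nuclei are segmented slice-wise in 2D and stitched across z, a strategy
suited to anisotropic confocal stacks of densely packed ~10 µm nuclei.

**Pre-processing.** Intensities are first equalised with 3D adaptive
histogram equalisation using a kernel cube of 10 µm per side — the
average nuclear diameter — converted to voxels per axis by rounding
`kernel_um / voxel_size`, so anisotropic stacks get anisotropic windows.
A difference-of-Gaussians band-pass (low σ = 1, high σ = 3) is then
applied and thresholded at 0. The σ values are interpreted in **voxel
units** by default, matching the unitless way such parameters are
usually quoted; a µm interpretation is available
(`dog_sigma_units="um"`). Because the nuclear profile is smooth rather
than a plateau, the DoG responds positively throughout the nucleus body,
not just at its rim.

**2D labelling.** The labeller is a pluggable callable
`(2D array) → 2D integer labels`, so a pretrained model can slot in.
The shipped reference backend is classical and weight-free: Gaussian
smoothing (σ = 1 px), Otsu threshold with an absolute floor
(`min_intensity = 0.02` of the equalised dynamic range — adaptive
equalisation amplifies numerically tiny residue in empty background,
and without the floor Otsu would split that noise into spurious blobs),
hole filling, removal of blobs below a plausible nucleus cross-section
(`min_area_fraction = 0.25` of the nominal equatorial area
π(D/2)²), and a distance-transform watershed seeded at distance maxima
to split touching nuclei.

**2D→3D stitching.** Scanning slices in increasing z, each 2D label is
matched to at most one label of the previous slice by greedy one-to-one
matching in descending intersection-over-union order (ties broken by
larger intersection, then lower 2D label id). Pairs with IoU ≥ 0.6
inherit the 3D label; everything else seeds a new label. IoU is
computed on the 2D pixel footprints of adjacent slices only — no gap
bridging. Raising the threshold can only remove candidate matches, so
the 3D label count is monotone non-decreasing in the threshold, and it
never exceeds the total number of 2D labels.

A geometric consequence of any fixed IoU threshold is worth recording:
for a convex nucleus, the cross-section area shrinks rapidly near its
poles, so the outermost ("cap") slice of a nucleus can fail the 0.6
criterion against the slice below it and become an orphan label. Two
mitigations are built in and on by default: the 2D backend's
plausible-area rule removes most cap cross-sections before stitching
(with a minimum area ≥ ~0.65 of the equatorial cross-section, the
surviving consecutive footprints of a ~10 µm nucleus provably satisfy
IoU ≥ 0.6, which is the regime in which stitching coincides exactly
with 3D connected-component labelling, as the test suite verifies), and
`segment_nuclei` finishes with a minimum-volume filter (default 20% of
the nominal nucleus volume) that removes any remaining orphan
fragments.

**Measurement.** Per-nucleus centroids use the voxel-centre convention
(voxel (0,0,0) centred at the origin; positions are 0-based indices
times the per-axis spacing), volumes are voxel counts times the voxel
volume, and per-channel means are plain averages over the label — so a
uniform channel yields exactly its constant value.

## Expression quantification

HCR channels are smoothed with two rounds of median filtering with a
0.8 µm kernel (the size of a nuclear transcription spot), converted to
the nearest odd voxel window ≥ 1 per axis. Background per channel is
the **median** nuclear mean intensity in a tissue where the gene is off
(*sox2* in notochord, *tbxta*/*tbx16* in spinal cord); the median makes
the estimate robust to stray bright nuclei. A nucleus is positive for a
channel when its mean intensity is **strictly** above background — ties
count as background, the conservative reading. Nuclei at background in
both genes are excluded with reason `background`; ids on an explicit
manual-exclusion list (e.g. hypochord nuclei identified by eye) are
excluded afterwards with reason `manual`, so manual curation is an
input, never hidden inside the algorithm.

For double-positive (NMC) nuclei the relative level is
`(a − b)/(a + b)` with `a = I_sox2 − bg_sox2`, `b = I_tbxta − bg_tbxta`,
each floored at 0. The form is chosen for its properties rather than
derived from a published formula: bounded in [−1, 1], antisymmetric
under swapping the genes, invariant to adding a constant offset to a
channel and its background, and strictly monotone in each input. When
`a + b = 0` the index is undefined and flagged (NaN), never silently
set to 0. Whether intensities should be z-normalised per embryo before
computing relative levels is an open question of the source protocol;
this implementation applies no per-embryo normalisation and records
that as its choice.

## Registration and neighbourhood mapping

Rigid transforms are proper rotations plus translation (optional
isotropic scale, default 1), validated to 1e-8 orthonormality. Landmark
mode solves the least-squares alignment in closed form (SVD/Kabsch);
geometry whose centred rank is < 3 is rejected. ICP mode alternates
nearest-neighbour matching with the closed-form update until the mean
residual changes by < 1e-8 µm (default) or 50 iterations;
non-convergence is flagged on the result rather than raised. Noiseless
recovery is verified to < 0.01° rotation and < 1e-4 µm translation
error. Intensity-aware correspondence (as in atlas tools with
expression-weighted matching) is not reproduced.

Neighbourhood averaging pools registered nuclei across embryos and, for
each reference point, averages an attribute over pooled points
**strictly within** 11 µm, excluding points exactly coincident with the
reference point (so pooling a cloud with itself does not average each
nucleus into its own neighbourhood; both conventions are recorded
choices, since neither strictness nor self-exclusion is standardised).
The 11 µm default corresponds to ~14 nearest neighbours for ~10 µm
nuclei — exactly the first two coordination shells of a perfect
body-centred cubic lattice (8 at √3/2 of the cell side plus 6 at one
cell side), a property the tests check exactly for any radius between
the second and third shells.

ROI bookkeeping uses axis-aligned boxes in µm, inclusive on the low
edge and exclusive on the high edge (so adjacent ROIs partition space);
overlap heatmaps count, per voxel (by its centre), how many registered
ROIs cover it.

## Track metrics

Track tables are consumed as exports (spot detection and linking are
out of scope): the generic `id/t/x/y/z` layout and the common
`TRACK_ID/POSITION_X/Y/Z/T/FRAME` layout are accepted, with exporter
unit rows dropped. Frame gaps of up to two missing frames are accepted
— matching the linking setting of the upstream tracker — and larger
gaps are an error; gaps are never interpolated, and MSD lag pairs
spanning a gap are skipped.

The per-track MSD is time-averaged,
`MSD(τ) = ⟨‖r(t+τ) − r(t)‖²⟩_t`, over frame lags 1 … ⌊(n−1)/2⌋ (half
the track length, the usual bias/variance compromise), and α is the
ordinary least-squares slope of log MSD vs log τ over all retained lags.
Lags with zero MSD are dropped; fewer than three surviving points make
α undefined (stationary tracks therefore have no exponent rather than a
spurious one). A track is called directional when α **strictly**
exceeds 1.1; α = 1.1 exactly is not directional. Calibration on
generated ensembles: diffusive mean α ≈ 1.0 (±0.1 at 200 tracks × 100
steps), noiseless ballistic α = 2 exactly, confined mean α < 1.

Two metrics stand in for quantities whose exact published formulas live
in prior literature, and are named to avoid implying equivalence:
**corrected straightness** is (net displacement / path length) × √(track
duration in frames) — the √duration factor corrects the systematic
decay of plain straightness with track length; 0/0 (stationary) is 0 by
convention — and **mean angular alignment** is the mean cosine of the
turning angle between consecutive steps (+1 straight, −1 reversing, ≈ 0
for an isotropic walk), with zero-length steps skipped.

Dorsoventral displacement is `(end − start)·dv_axis` with
ventral-positive sign fixed once in the config; the per-embryo ventral
fraction considers tracks starting strictly within 60 µm of the
reference point (ablation centre or control-equivalent). Reporter
dynamics are the per-embryo z-scored start intensity and the mean of
successive intensity differences (which telescopes to
`(I_last − I_first)/(n−1)` on gap-free tracks).

All motion metrics are invariant under global rigid motion of the track
set (DV displacement transforms with the axis, as it should).

## Morphometrics and statistics

Tissue lengths are piecewise-linear sums along 2D segmented-line
polylines — no spline smoothing, matching how such measurements are
made interactively — with landmark indices marking somite boundaries,
so per-somite segments are exact and total = Σ segments holds to
machine precision. Lengths are normalised to µm/somite by dividing by
the total somite count; the spinal-cord/paraxial-mesoderm ratio divides
totals measured from the same anterior landmark. Apoptosis fractions
are percentages of marker-positive nuclei.

Group comparison is the two-sided Mann–Whitney–Wilcoxon test. For
combined n ≤ 20 the p-value is exact by full enumeration of all
`C(n_a+n_b, n_a)` group assignments on midranks, two-sided via the
deviation `|U − n_a n_b/2|`; this handles ties correctly and matches an
independent pairwise-counting permutation oracle in the tests. Larger
samples use the normal approximation with tie correction. Whether the
original analyses were exact or asymptotic, one- or two-sided, is not
stated anywhere authoritative; two-sided with the n = 20 switch is this
package's recorded convention. Significance tiers are inclusive:
\*P ≤ 0.05, \*\*P ≤ 0.01, \*\*\*P ≤ 0.001, \*\*\*\*P ≤ 0.0001.

## Synthetic data: what it emulates, and what it does not

The phantom generator places ~10 µm Gaussian-tapered ellipsoidal nuclei
(per-axis semi-axes jittered by ×[0.9, 1.05]) inside the ellipsoid
inscribed in the requested volume (a rounded, tailbud-like domain),
with centre-to-centre separation at least 0.8 × diameter (raise
`min_separation_factor` to guarantee non-touching nuclei for
segmentation benchmarks). Expression amplitudes follow the dorsoventral
coordinate g ∈ [0, 1]: sox2 decreases and tbxta increases linearly with
g, each gene expressed only up to / from the co-expression band (default
g ∈ [0.4, 0.6]), with a 0.3 amplitude floor so in-band nuclei are
unambiguously double-positive. Ablated regions replace nuclei with 3–6
bright 1–3 µm fragments, mimicking pyknotic debris. Noise is additive
Gaussian with a Poisson-like signal-dependent scale,
`sd = noise_sd·√(1+I)`; bit depth and camera statistics of the real
microscopes are unknown, so the default is noiseless and `noise_sd` is
a testability knob, not a fidelity claim.

Track simulation: diffusive = i.i.d. Gaussian steps (true α = 1);
ballistic = constant random velocity plus optional positional noise
(true α = 2); persistent = AR(1)-correlated steps; confined = diffusive
steps reflected at a sphere (α < 1 at long lags). Point clouds are
uniform draws mapped by random bounded rigid transforms plus isotropic
jitter. Tail polylines chain one exact-length chord per somite with
small random heading changes (5° sd), plus a 4-chord PSM stretch.

Every generator is a pure function of its spec including the seed, and
each output carries enough ground truth (labels, classes, exponents,
transforms, lengths) that downstream recovery error is computable
without reaching into generator internals.

**What passing tests do not show:** the phantoms have no point-spread
function, bleaching, tile seams, optical sectioning crosstalk or real
nuclear texture; nuclei are convex and mono-sized; tracks have no
localisation error model beyond additive Gaussian noise. Passing the
suite demonstrates the *algorithms* are correct at their operating
points, not that the defaults are optimal on any particular microscope's
data.

## Problem sizes and defaults

The reference benchmarks use 50-nucleus phantoms on a 40×120×120 voxel
grid at 1 µm isotropic spacing, 200-track ensembles of 100 steps for
MSD calibration, 100 random transforms for registration recovery, and
20 phantoms for the stitching/connected-components equivalence check —
sizes chosen so the whole suite runs on a laptop-class single core in
well under a minute per check while keeping sampling error far from the
test tolerances.

## Known limitations

- The 2D reference labeller is classical; heavily overlapping or highly
  textured nuclei will need a trained backend via the adapter slot.
- Stitching bridges no gaps: a nucleus invisible in one intermediate
  slice splits in two (by design, the simplest reading of slice-wise
  joining).
- Registration is rigid (+ optional isotropic scale); deformable
  alignment and atlas construction are out of scope.
- Division linkage is carried through track IO but lineage analysis is
  not implemented.
- Manual steps of the original workflows (hypochord removal, division
  counting, somite-contribution scoring) enter only as explicit
  exclusion/count inputs.
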