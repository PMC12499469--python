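# Methods

This note documents the models, defaults and numerical choices behind
`mrcquant`, and what the synthetic-data suite does and does not establish
about real microscopy data.

## Synthetic microscopy model

The generator (`mrcquant.simulate`) emulates the imaging side of a
molecular-recruitment-colocalization experiment, not its biology.

**Geometry and optics.** Nuclei are disks laid out on a grid; puncta are 2D
Gaussian point-spread-function profiles with `psf_sigma = 1.6 px` at a pixel
size of `0.08 µm/px` (≈130 nm PSF sigma, consistent with a 100×/1.4 NA oil
objective; the acquisition hardware this emulates does not pin down a pixel
size, so these are package defaults, chosen once). Spot centres are snapped
to pixel centres so that the rendered peak equals the configured amplitude
exactly, which gives downstream oracles (peak, SNR, centroid) exact expected
values on noise-free images. Condensates are disks — or area-preserving
ellipses for low-circularity truth — with a soft erf edge of width
`psf_sigma`, the exact profile of a hard disk convolved with a Gaussian PSF.

**Channels.** Channel 0 (bait) receives the sampled number of puncta per
nucleus (`spots_per_cell`: a fixed count or a distribution over counts);
channel 1 (prey) receives a partner at the same centroid with probability
`coloc_fraction` and amplitude ratio `prey_to_bait_ratio`. Placement rejects
positions closer than 4·`psf_sigma` so spots never blend.

**Noise.** Default `gaussian`: additive N(0, `bg_sd`²) everywhere, which
makes the background statistics of the SNR definition exact by construction.
`poisson+gaussian` adds Poisson shot noise on the expected intensity plus
Gaussian read noise for more camera-like images. `none` disables noise for
exact oracles. No EMCCD gain calibration is modelled.

**FRAP forward model.** Pre-bleach plateau (default 100 a.u.), instantaneous
bleach to `plateau·(1 − bleach_depth)` at t = 0 (the bleach pulse is not
temporally resolved), then recovery `A(1 − e^{−t/τ})` of the bleached
amount. A linear drift (shared by the bleached and control traces) and
Gaussian noise are optional. The drift is referenced to the pre-bleach
baseline — it averages to zero over the pre-bleach frames — representing an
acquisition that starts on a calibrated plateau; with this convention,
control-anchored drift subtraction removes a shared drift exactly, which the
tests exploit.

**Trajectories.** 2D random walks with per-axis step variance `2·D·dt`, so
the free-motion MSD is `4·D·τ`. Defaults follow a typical quantum-dot
tracking protocol: `dt = 0.1 s`, 100 frames (10 s total). Confinement is
implemented as radial reflection at a circular boundary — the simplest
mechanism that reproduces an MSD plateau and a subdiffusive apparent
exponent; it is not a model of condensate viscoelasticity.

**What passing tests do not show.** The generator has flat backgrounds,
isolated cells, no autofluorescence, no chromatic shift, no stage drift in
images, no bleaching during acquisition (outside FRAP), and spots never
overlap. Detection and estimation results on these images bound what the
algorithms can do under their own assumptions; they do not certify
performance on real micrographs.

## Spot detection

Laplacian-of-Gaussian filtering at the PSF scale, local maxima inside the
nuclear mask, merging of maxima closer than 2·`psf_sigma` (brighter wins),
then an intensity gate `peak > bg_mean + threshold_k·bg_sd` with the
background estimated from nuclear pixels excluding dilated candidate
neighbourhoods. `threshold_k = 5` by default — a conservative gate that in
the acceptance suite yields recall ≥ 0.95 at spot SNR ≥ 10 with a
false-positive rate ≤ 0.05. Spot area is the above-threshold connected
component containing the peak; centroids are intensity-weighted over a
(2·`psf_sigma`)-radius window and reported in µm. Detection operates on
maximum-intensity projections by default. Because both the peak and the
background statistics shift equally, detection is invariant under adding a
constant to the whole image.

## SNR and colocalization

`spot_snr` implements `(peak − background mean) / background SD` with the
background taken from a disk of `bg_diameter_um = 3.5 µm` (middle of the
conventional 3–4 µm range) centred on the measured spot, minus a
2·`psf_sigma` disk around every labelled spot including the measured one; at
least 50 background pixels are required. The statistic is exactly invariant
under positive affine intensity transforms.

Matching is greedy nearest-neighbour, closest pair first, one use per spot,
with `max_dist_um = 0.3 µm` by default (~2–3 px at the default pixel size;
exposed and recorded in output metadata, since merged-spot judgements by eye
do not define a distance). Greedy matching coincides with the optimal
assignment when inter-locus distances are large relative to the match
radius — the operating regime of genomic recruitment sites, and the regime
in which the brute-force equivalence test runs; in adversarially dense
fields greedy can match fewer pairs than an optimal matcher. Cells with zero
bait spots are excluded from per-cell colocalization averages. The SNR ratio
is reported bait/prey.

Pixel-wise colocalization offers Pearson r and Manders M1/M2 with
per-channel thresholds (default: in-mask channel means). No Costes
randomization test is included.

## Condensate morphometrics

Segmentation thresholds at `bg_mean + threshold_k·bg_sd` (default k = 3)
inside the nuclear mask. The background is estimated by a median/MAD-anchored
sigma clip, which converges to the background population even when bright
condensate pixels dominate the plain SD. On effectively noiseless images the
k·SD band collapses onto the background and would segment the faint PSF-tail
skirt; the threshold then falls back to the half-maximum level, which marks
the true edge of a soft-edged disk.

Perimeter uses the Crofton estimator (raw pixel-edge counting inflates
perimeter and deflates circularity); circularity `4π·area/perimeter²` is
clamped to [0, 1]. On the analytic circle the formula gives exactly 1; a
rasterized noise-free disk of radius 20 px measures ≥ 0.95. "Log-normalized"
areas are areas in µm² divided by a configurable normalization constant
(default 1 µm²), then log10 — the constant is recorded in output metadata.
Objects are classified "condensate" iff area ≥ 0.5 µm² AND circularity
≥ 0.8 (both exposed). Morphology alone is not treated as proof of
liquid–liquid phase separation.

## FRAP analysis

Order of operations: subtract the control trace re-anchored to its own
pre-bleach mean, then divide by the pre-bleach mean of the corrected trace
(the pre-bleach reference statistic is the mean of all pre-bleach frames).
`R_norm` therefore maps the pre-bleach plateau to 1 and the first
post-bleach frame to its fraction of pre-bleach. Fractional recovery
normalizes the post-bleach segment to [0, 1]; a bleach depth below 10⁻³ is
rejected as too shallow. At least 3 pre-bleach and 5 post-bleach frames are
required.

The single-exponential fit uses nonlinear least squares with A₀ = final
fractional recovery, τ₀ = first time the recovery passes A₀/2, and bounds
A ∈ [0, 1.5], τ ∈ (0, 10·t_max]. A is deliberately allowed slightly above 1
to avoid boundary bias under noise; fits with A > 1 are flagged rather than
clipped. `percent_recovery = 100·A` holds to machine precision by
construction, and `1 − A` is reported as a convenience immobile fraction.
Non-convergence returns a flagged result instead of raising. Per-trace fits
are averaged per condition (rather than fitting the averaged curve). No
reaction–diffusion FRAP models are provided.

## Single-particle MSD

Time-averaged MSD per trajectory up to 1/4 of its length (`max_lag_fraction`
= 0.25); for a gap-free track of length L, lag k averages L − k pairs.
`D_eff` is the through-origin least-squares slope over the first 4 lags
divided by 4 — through the origin because the model has MSD(0) = 0 and no
localization-error offset term (an offset mode exists but is off by
default). α is the log-log slope over the same lags; regime thresholds are
0.9 and 1.1. Inside/outside-condensate comparison uses a Welch t-test with a
direction flag; group variances that are both numerically zero are reported
as degenerate rather than fed to the t-statistic. Linking is greedy
nearest-neighbour frame to frame with a maximum displacement per frame and
optional gap bridging; inside/outside labels come from a condensate mask by
majority vote over the trajectory's positions (exact ties stay unlabeled).

## Statistics and pipeline

Two groups: Welch t-test by default (the unequal-variance form is the safer
choice when variances are unknown; classical Student is available by flag).
More than two: one-way ANOVA then Tukey HSD (statsmodels) with an
insert-and-absorb compact-letter display — groups sharing a letter are not
significantly different at the chosen α. Significance stars at
0.05/0.01/0.001. Beyond Tukey, no multiple-testing adjustment is applied
across conditions; the report says so.

The pipeline derives every stage seed from the base seed via SHA-256 (all
derived seeds < 2³¹), embeds the config hash and package version in the
report, and is byte-identical under a fixed config + seed. Replicate
structure defaults to 3 replicates × 15 cells per condition, a typical
design for this assay family.

## Problem sizes

Simulation-backed checks use sizes at which their statistical tolerances are
comfortably resolvable: 500 tracks × 100 steps for diffusion-coefficient
recovery (10% tolerance), 200 noisy traces for FRAP bias (±0.03 on A), 100
cells for detection recall/FPR, 3 × 15 cells for colocalization estimates,
1000 null datasets for the ANOVA type-I-error check, and 20 seeded runs for
the confined-versus-free power check.

## Known limitations

- The condensate area measured at `k·SD` above background depends on the
  noise level through the threshold crossing on the soft edge; areas are
  comparable within a condition, and ratio-based statements (e.g. log-area
  differences) are most reliable on images acquired — or generated — under
  matched conditions.
- Greedy linking and matching are not globally optimal in crowded scenes.
- The SNR-ratio binding proxy is relative, not an affinity: PSF tails raise
  local background estimates and amplitude ratios propagate nonlinearly, so
  only comparisons between conditions measured the same way are meaningful.
- Confinement by reflection reproduces the MSD plateau but not binding or
  viscoelastic subdiffusion mechanisms.
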