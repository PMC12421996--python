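# Methods

## Scope and design

The package quantifies transient contacts ("kissing") between mobile protein
condensates and a stationary RNA transcriptional burst in two-channel
time-lapse microscopy, and the 3D geometry of such foci relative to the
nuclear boundary in fixed-cell z-stacks. All physical quantities are in µm
and seconds; arrays are ordered `(t, channel, y, x)` for movies and
`(channel, z, y, x)` for volumes, voxel centres at integer indices, 0-based.

## Synthetic-data generator

The generator stands in for raw microscopy and defines the conditions under
which the pipeline is validated.

**Motion model.** The condensate follows a discrete Ornstein–Uhlenbeck (OU)
process tethered to the burst position c:

    x_{t+1} = c + a (x_t − c) + σ √(1 − a²) ξ_t,   a = exp(−Δt/τ)

with ξ_t standard normal per axis. This is the exact discretisation, so the
per-axis stationary SD is σ (`tether_sd_um`) and the relaxation time is τ
(`tether_relaxation_s`) regardless of the frame interval; the walk starts
from a stationary draw. OU tethering is the simplest stationary confined
process consistent with to-and-fro motion that stays within ~1 µm of the
burst; with the default σ ≈ 0.296 µm, P(distance ≤ 1 µm) > 0.99. For an
isotropic 2D tether the distance is Rayleigh, so the contact occupancy at
threshold r is P(d ≤ r) = 1 − exp(−r²/2σ²); `tether_sd_for_contact_fraction`
inverts this, and the default corresponds to 30% occupancy at the 0.25 µm
contact threshold. τ defaults to 5 s, which reproduces separation→contact
transitions on the few-second timescale seen in such recordings.

**Intensity exchange.** During frames whose true centre distance is at or
below the contact threshold, a fraction `exchange_rate` of the current RNA
intensity moves to the condensate before the next frame; independent
Gaussian fluctuation noise (`intensity_noise_sd`) is added to the observed
series afterwards. Without fluctuation noise the channel sum is conserved
exactly. This contact-gated mass transfer is the minimal generative
mechanism for the negative Pearson correlation between the two channels; it
deliberately does not distinguish transfer from transcription shut-off,
defocus or photobleaching, which produce the same signature in real data
and cannot be separated by this analysis.

**Image formation.** Each object is rendered as a Gaussian of width
`psf_sigma_um` integrated over pixels (separable erf differences), scaled so
the frame's summed pixel value equals the object's intensity up to field
truncation. Poisson noise is applied first, then additive Gaussian read
noise. A PSF below 0.25 pixel triggers an undersampling warning. No optical
realism beyond this (no bleed-through, no bleaching kinetics, no STED
depletion) is attempted.

**Fixed volumes.** One ellipsoidal nucleus (semi-axes configurable, default
4.2 × 5.5 × 5.5 µm) is voxelized at the acquisition anisotropy (default
0.3 µm z-step, 0.1 µm in-plane). Foci are placed by stepping inward from a
random surface point along the inward normal and their *exact* analytic
boundary distance is recorded, computed by the standard Lagrange-parameter
root for the nearest point on an ellipsoid (bisection; an independent
brute-force surface-sampling oracle verifies it in the tests to <5 nm).
Condensate rim distances default to a truncated exponential (mean 0.4 µm,
max 2.5 µm), concentrating foci near the nuclear periphery as observed for
both bursts and condensates in this system; one RNA focus per nucleus is
assigned the largest total intensity and recorded as the true burst.

Identical seeds give bit-identical movies, volumes and truth ledgers; all
randomness flows through one `numpy` Generator per run.

## Detection and localization

Foci are detected on the scale-normalised negative Laplacian of Gaussian
(σ_px = `scale_um`/pixel size per axis, so anisotropic volumes are handled
natively). The response threshold adapts to image noise as
`k_sigma` (default 6) robust sigmas (1.4826 × MAD) of the response, with a
floor of 10% of the maximum response for noiseless images. Candidate maxima
closer than 2σ are suppressed. Spot statistics are measured on a ±4σ window
after subtracting the frame median background: sum intensity (equal to the
rendered mass within 2% for a noiseless spot), peak intensity, and size as
the area/volume above half the background-subtracted peak (minimum 2 pixels
live / 4 voxels fixed, configurable). Centres are intensity-weighted
centroids of the clipped window — accurate to well under 0.05 pixel on
noiseless renders; a window with zero net intensity keeps the integer
maximum and raises a low-confidence flag.

Nuclei are segmented classically: Gaussian smoothing (0.3 µm) → Otsu
threshold → hole filling → removal of components below 5 µm³ → labelling.
This replaces interactive/learned surface creation with a deterministic,
fully specifiable procedure; a blank channel raises a "no nucleus found"
error rather than returning an empty mask.

The transcriptional burst is the RNA spot with maximal sum intensity per
nucleus; ties break by larger size, then lowest label, making the rule
permutation-invariant. In live mode the rule extends over time: the burst
track is the RNA track with the highest mean sum intensity over real
(non-interpolated) detections.

## Tracking

Each frame is linked to open tracks by exact optimal assignment
(`scipy.optimize.linear_sum_assignment`) over candidate pairs within the
displacement gate (`max_disp_um`, default 0.5 µm/frame, scaled by the gap
length across missing frames). The assignment maximises the number of links
and, among those, minimises total displacement — identical to exhaustive
enumeration at these problem sizes (a handful of objects per frame). A
greedy mutual-nearest-neighbour linker was evaluated first and agreed with
the enumeration oracle on only 94% of random small instances; the exact
assignment agrees by construction, at negligible cost. Linking is always
within one channel. Gaps up to `max_gap` frames are bridged by linear
interpolation of centre and intensity, with bridged frames flagged so
downstream statistics exclude them; longer gaps split the track. Because the
OU motion occasionally jumps more than the gate in one frame, a single
physical object may yield several track segments; movie-level statistics
therefore aggregate over all condensate segments.

## Kissing dynamics

The distance trace is the Euclidean centre distance per common frame of the
condensate and burst tracks; frames are valid only where both tracks carry
real detections. Episodes are maximal runs of valid frames with
d ≤ 0.25 µm: the boundary is inclusive ("0.25 µm or less"), no hysteresis is
applied (a single threshold both ways is the literal operational
definition), one-frame "hit-and-run" contacts count, and invalid frames
terminate runs rather than being bridged — contacts are never fabricated
from interpolated positions. Approach (peak-to-valley) events take each
local distance maximum above threshold (3-frame neighbourhood) and the first
subsequent valid frame at or below threshold; the transit time is their
separation. Pearson r between the intensity series uses the sample
correlation with a two-sided t-distribution p on n−2 df; constant series and
n < 3 raise typed errors rather than returning NaN.

## Co-localization

Object-based: a query focus is co-localized when its nearest target centre
is ≤ 0.25 µm away (inclusive). Fractions are per cell (`nucleus_id`),
aggregated as mean ± SEM across cells; cells without query foci contribute
no fraction. Signal-based: the voxelwise AND of per-channel exceedance
masks, thresholds defaulting to per-channel Otsu (the instrument-software
defaults such analyses typically rely on are not specifiable, so the
threshold is exposed and the Otsu default documented). The overlap channel
is symmetric and associative, and raising any threshold never adds overlap
voxels. The three-way variant additionally reports whether any overlap
voxel falls inside a nucleus. Edge overlap with centre separation > 0.25 µm
is expected behaviour, not a contradiction: pixel overlap probes object
peripheries, the object-based test probes centres.

## Nuclear-rim geometry

Boundary distances are exact Euclidean distances from each focus centre to
the *interface midpoint cloud*: the midpoints of every axis-adjacent
inside/outside voxel pair, in physical units. A binary mask localises its
surface no better than half a voxel along the normal, and this estimator
attains that limit; a distance transform to background voxel centres was
evaluated first and overestimates by up to a full voxel along the normal
(0.3 µm in z), which is why the midpoint construction is used. Validated
error: ≤ 0.147 µm maximum over 10 × 500 foci against the analytic ellipsoid
oracle at 0.3/0.1/0.1 µm voxels. Foci whose nearest voxel lies outside all
nuclei are excluded and counted.

"Within 1 µm" is a strict `<` comparison, applied uniformly. The near/far
brightness comparison takes condensates within the cutoff of their
nucleus's burst as "near" and all other in-nucleus condensates as "far",
and runs Welch's unequal-variance two-sided t test (the safer default when
only "unpaired two-tailed t test" is specified); degenerate zero-variance
groups are defined explicitly (equal means → t = 0, p = 1). Outlier
flagging, where requested, uses the transparent median/MAD rule: flag
|x − median| > k · 1.4826·MAD (k = 3.5), falling back to the mean absolute
deviation (×1.2533) when the MAD degenerates to zero with deviations
present, never dropping more than 10% of points (ceiling, so one point may
be dropped from small samples). This replaces proprietary robust-regression
outlier tests that are not fully specified outside their host software.

## Pipelines, determinism, reporting

`run_live_pipeline` and `run_fixed_pipeline` chain the stages, write every
numeric report field to a stage CSV as well, and embed the config hash and
package version. Reports contain no timestamps, so identical input and
config give byte-identical output. Live traces are truncated at the last
confident detection — frames where a signal disappears are simply absent
rather than extrapolated.

## Validation problem sizes

The test suite and `scripts/acceptance.py` validate under these conditions:
50 movies × 300 frames at 1.04 s (noiseless rendering, 30% contact
occupancy) for contact-schedule recovery; 100 seeds × 1000-frame intensity
series for the anti-correlation sign and its null calibration (the null
|r| < 0.1 criterion needs series of this length: the null r SD is 1/√n);
5 volumes × ~100 foci for rim geometry (≈500 foci, binomial CI at n = 500);
200 random small instances for the linking oracle, 1000 random traces for
the episode scan, 1000 configurations for nearest-neighbour brute force;
100 noise seeds at SNR 10 for detection recall/precision; 200 seeds for the
Welch-test power study. The full acceptance run takes ~30 s on one CPU.

## Known limitations

* The simulator's exchange mechanism is one of several processes that
  produce anti-correlated intensities in real data; passing sign-recovery
  tests demonstrates the pipeline detects the signature, not that real
  anti-correlation implies material transfer.
* Gaussian-PSF rendering omits bleed-through, bleaching and depth-dependent
  aberrations; detection thresholds tuned on synthetic noise may need
  adjustment on real instruments (all are exposed in `PipelineConfig`).
* Linking assumes no splitting/merging and no motion-model prediction;
  adequate for a few well-separated objects, not for dense fields.
* Condensate area is reported alongside intensity but no mechanism linking
  the two is modelled.
* Rim distances inherit the half-voxel-per-normal information limit of
  binary masks; a 0.3 µm z-step bounds accuracy at ±0.15 µm near the poles.
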