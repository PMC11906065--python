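# Methods

## Perfusion model

A blood-borne fluorophore bolus reaching a tissue region (or a bench flow
chamber) produces an intensity time-course with a rapid wash-in as the dye
first arrives and a slower exponential wash-out as it clears. The simulator
and the feature extractor both use the minimal two-rate form

    I(t) = A · (1 − exp(−k_in·τ)) · exp(−k_out·τ),   τ = t − t_arrival,  I = 0 for τ < 0

with wash-in rate `k_in` (1/s), wash-out rate `k_out` (1/s, `k_out < k_in`),
arrival time `t_arrival` (s) and amplitude `A` (fraction of the sensor's
dynamic range). The curve is continuous at onset, has a single interior
maximum at `τ* = ln((k_in+k_out)/k_out)/k_in`, and tends to zero. This
rise×decay product is the simplest form with independent wash-in and
wash-out rates, which map directly onto the two inlet/outlet orifice sizes
of a dual-chamber bench rig; no fluid-dynamic conversion from orifice
diameter to rate constant is attempted.

## Margination pipeline

**Channel isolation.** NIR emission leaks predominantly into one channel of
a colour sensor. The automatic strategy picks the channel with the largest
summed per-pixel temporal variance; the bolus transient dominates temporal
variance in whichever channel carries it. Grayscale conversion is channel
isolation, not luma mixing — mixing would dilute the signal with channels
carrying none. A fixed-index override exists for sensors with known layout.

**Foreground thresholding.** The per-pixel statistic thresholded is the
temporal *maximum* (default), so pixels whose wash-in arrives late are
kept; mean and peak-to-peak range are available. The threshold defaults to
a fraction (0.2) of the dtype range, making it bit-depth independent.
Whether the original bench analysis thresholded per-frame or per-video is
not documented; a per-video temporal statistic was chosen because the
downstream stages operate on whole traces.

**PCA.** Pixel traces are centered and projected onto the smallest number
of principal axes reaching 99 % explained variance, capped at 10
(configurable). Phantom dynamics are low-rank — a handful of curve families
— so the cap is generous. The eigendecomposition route
(`svd_solver="covariance_eigh"`) is deterministic; component sign is fixed
by making the largest-magnitude loading positive.

**k-means.** Default k = 4: two perfused regions plus headroom for
background/transition pixel populations. k-means++ seeding, best of 10
restarts by inertia, seeded — the seed is a required, logged parameter of
every pipeline run. Cluster-center time-series are computed as per-cluster
means of the *original* traces, not PCA reconstructions, so the correlation
stage is independent of the PCA choice. An empty cluster after convergence
raises rather than silently proceeding.

**Cluster selection.** The two "most chamber-representative" clusters are
the two with the highest accumulated fluorescence — the sum of the center
trace over frames (area under the curve at unit spacing). Ties break toward
the lower cluster id.

**NCC.** For equal-length signals, `NCC = 1/(T−1)·Σ ((a_t−ā)/s_a)((b_t−b̄)/s_b)`
with sample (T−1) standard deviations; the matching denominators make
`ncc(a,a) = 1`. Internally the (T−1) factors are cancelled and the value
computed as `(da·db)/√((da·da)(db·db))`, which is algebraically identical
and makes the self- and anti-correlation identities exact in floating
point. Zero-variance traces are *excluded* (marked missing), not scored 0:
the formula is undefined there and silent zeros would bias the difference
map. NCC is invariant to positive affine rescaling of either signal, so the
dim rim of a chamber correlates with its core exactly as the core does.

**Margination.** `NCC_diff = NCC_C1 − NCC_C2`; region 1 is `> +ε`, region 2
`< −ε`, and the margin `|NCC_diff| ≤ ε` with ε = 0.05 by default — a small
band around zero that renders as a thin margin between regions. ε is not
documented for the original bench analysis; 0.05 is this package's default
and is configurable. An optional largest-4-connected-component filter per
region is provided but off by default. Whether the pixel traces fed to the
NCC should be raw or PCA-denoised is equally undocumented; raw traces are
used so the correlation stage stands on its own.

## Synthetic phantom

The generator emulates a dual-chamber perfusion bench: two rectangular (or
elliptical) chambers in a 480×640 frame, 20 s at 30 fps, each carrying its
own kinetic curve. Defaults: fast chamber `k_in 1.5/s, k_out 0.15/s,
arrival 1.5 s`; slow chamber `k_in 0.5/s, k_out 0.05/s, arrival 2.5 s`;
amplitude 0.75 of range; background level 10/255; Gaussian read noise
sd 2 (8-bit units) and optional Poisson shot noise, both seeded; channel
gains (1.0, 0.3, 0.1) inject the signal predominantly into the red channel
to exercise channel auto-selection. The two rate-constant pairs are package
choices giving clearly distinct wash-in/wash-out profiles — they stand in
for the two orifice sizes of the physical rig and are not measurements, and
the video duration/pump rate of the bench sessions are likewise not
documented, so 20 s is a package choice.

Each chamber renders a bright core plus a rim band (width 12 px, gain 0.35
of the core amplitude) along the chamber wall: the optical path through a
fluid channel is shorter near the wall, so wall-adjacent pixels carry a
scaled-down copy of the same curve. This gives the scene four genuine pixel
populations (two cores, two rims) — mirroring real scenes where clustering
sees chambers plus dimmer transition regions — while leaving every chamber
pixel NCC-equivalent to its core (NCC is scale-invariant). Ground truth
returned with every render: full chamber masks and the noiseless
dominant-channel core trace of each chamber, quantized exactly as the
render is, so a noise-free render reproduces it bit-for-bit.

What the phantom does **not** model: optical point-spread/fibre-bundle
honeycomb artifacts, tissue scattering, motion, flat-field variation,
partial-volume blur at chamber edges (the rim is a step, not a gradient),
or restrictor hydrodynamics. Consequently a perfect Jaccard score on the
phantom shows the pipeline's correctness on step-edged, static, low-noise
scenes — not expected performance on hand-held clinical video, where
boundaries are soft and manual reference outlines are themselves imprecise.

## ROI tracking features

The single-ROI tracker averages the isolated channel over the ROI per frame
and smooths with a 5-frame moving average (edge-padded) before feature
extraction. Features: peak value; time-to-peak refined by a quadratic
vertex fit over the samples within 0.5 % of the peak (a bare argmax is
biased on slow curves whose quantized maximum is a plateau); wash-in slope
across the interpolated 10–90 % rise; wash-out constant from a log-linear
fit of the post-peak, baseline-subtracted tail restricted to (5 %, 80 %) of
the peak span — the upper cut skips the region still shaped by the
saturating rise, keeping the fit's bias well under the 5 % documented
recovery tolerance. Flat traces yield zero slope and zero decay constant.

## Numerical and interface conventions

- Angles cross the optics API in degrees; radians are internal. All optics
  functions return full precision; rounding is display-side.
- The Rayleigh contrast threshold for the resolution limit defaults to
  0.264 and is applied to a linear CTF-vs-frequency fit; the fitted form is
  an assumption (the original fit's form is not documented) and the
  threshold is a parameter.
- Coordinates are 0-based (row, col), origin top-left; rectangles
  half-open. Masks are {0,1} in memory and 0/255 PNG on disk.
- 640×480 @ 30 fps is the default working format; every operation accepts
  arbitrary sizes and rates.
- Pixel traces are float32 (memory: ~276 MB for a full-size phantom's
  foreground); NCC map accumulation and cluster centers are float64.
- The simulator draws noise in fixed 64-frame chunks so output is
  bit-identical for a given seed regardless of memory conditions.
- Batch evaluation resolves the arbitrary predicted-region numbering by the
  pairing with maximal total Jaccard; an exact tie keeps identity pairing
  and logs a warning. Margin-band pixels are excluded from predicted region
  masks by construction. Summary statistics are taken over all
  (video, chamber) entries.
- The nine-video phantom study in `scripts/acceptance.py` and the test
  suite runs full-size videos (480×640, 600 frames) one at a time; the
  unit-test phantom is 120×160 at 10 fps for speed.

## Known limitations

- Quasi-static scenes only: no motion compensation or registration.
- Exactly two regions are delineated (the NCC-difference construction is
  pairwise); more regions would need a different comparison scheme.
- k and d defaults are package choices; severely different scene structure
  (many regions, strong gradients) may need retuning.
- AVI/MP4 support depends on an imageio codec plugin being present;
  lossless TIFF/PNG paths are the tested interchange formats.
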