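# icgmargin

Full field-of-view quantification of indocyanine green (ICG) fluorescence
angiography video, with automatic delineation ("margination") of regions that
differ in perfusion dynamics.

## The problem

ICG is a clinically approved near-infrared fluorophore used as a blood-borne
perfusion indicator: after an intravenous bolus, tissue fluorescence rises
rapidly as the dye first arrives (wash-in) and then decays exponentially as
it clears (wash-out). Differently perfused tissue — or, on a bench rig, flow
chambers fed through different orifice sizes — produces distinct
intensity-vs-time profiles. Classic analysis tracks a single hand-drawn ROI,
which requires an experienced user; this package instead analyses *every*
foreground pixel's time-series and delineates regions of distinct perfusion
automatically.

## The algorithm

Given a colour fluorescence video with frames at times `t = i / fps`:

1. **Pre-processing** — isolate the colour channel carrying the NIR signal
   (largest summed temporal variance, or a fixed index), then keep pixels
   whose temporal maximum exceeds a threshold (default 0.2 of the dtype
   range), discarding background and non-dynamic fluorescence.
2. **Clustering** — reduce the N×T matrix of pixel traces with PCA (smallest
   d reaching 99 % explained variance, capped at 10), run k-means (default
   k = 4, k-means++, 10 restarts, fixed seed), and compute each cluster's
   center time-series as the mean of its member traces in original intensity
   space. Select the two clusters with the highest accumulated fluorescence
   (area under the center curve).
3. **Margination** — score every pixel trace against each selected center
   with the normalized cross-correlation

       NCC = 1/(T−1) · Σ_t ((a_t − ā)/s_a) · ((b_t − b̄)/s_b)

   (s are sample standard deviations; NCC is 1 for identical signals, −1 for
   negated ones). The difference map `NCC_diff = NCC_C1 − NCC_C2` splits the
   foreground into region 1 (`> +ε`), region 2 (`< −ε`) and the margin
   between them (`|NCC_diff| ≤ ε`, default ε = 0.05).

Delineated masks are scored against reference masks with the Jaccard index
`J(A,B) = |A∩B| / |A∪B|`. A synthetic dual-chamber perfusion phantom
(rise×decay bolus curves `A·(1−e^{−k_in τ})·e^{−k_out τ}` with per-chamber
rate constants, seeded sensor noise, ground-truth masks) provides desk-scale
validation, and an `optics` module collects the bench characterization
formulas (AFOI, Michelson CTF with Rayleigh-criterion resolution, SNR,
dB attenuation).

## Worked example

```python
import numpy as np
from icgmargin import (default_bench_phantom, generate_phantom, run_pipeline,
                       PipelineParams, evaluate_batch, track_roi, RoiSpec)

config = default_bench_phantom(seed=0)          # 480×640, 20 s @ 30 fps
video, truth = generate_phantom(config)
result, clustering, matrix = run_pipeline(video, PipelineParams(seed=0))

report = evaluate_batch([result], [tuple(truth.chamber_masks)])
print(f"foreground pixels: {matrix.n_pixels}")
print(f"PCA components kept: {clustering.embedding.shape[1]} "
      f"(explained variance {clustering.explained_variance_ratio.sum():.4f})")
print(f"cluster AUC scores: {np.round(clustering.auc, 0)}")
print(f"chamber Jaccard vs truth: {[f'{s:.3f}' for _, _, s in report.per_chamber]}")

roi = RoiSpec(shape="rectangle", rectangle=(100, 100, 180, 540))
trace = track_roi(video, roi)
print(f"fast chamber: time to peak {trace.time_to_peak:.2f} s, "
      f"peak {trace.peak_value:.1f}, wash-in slope {trace.wash_in_slope:.1f}/s, "
      f"wash-out k = {trace.washout_decay_constant:.3f}/s")
```

prints

```
foreground pixels: 115200
PCA components kept: 2 (explained variance 0.9971)
cluster AUC scores: [25755. 62444. 38381. 17334.]
chamber Jaccard vs truth: ['1.000', '1.000']
fast chamber: time to peak 3.11 s, peak 146.8, wash-in slope 130.2/s, wash-out k = 0.150/s
```

The 115 200 foreground pixels are the two chamber footprints; two principal
components carry essentially all temporal variance because the scene contains
two kinetic curve families; the two highest-AUC clusters are the chamber
cores, and the NCC-difference margination recovers both chamber masks exactly
on this scene. The ROI trace recovers the configured fast-chamber kinetics
(k_out = 0.15/s, closed-form peak at `t_arrival + ln((k_in+k_out)/k_out)/k_in
≈ 3.10 s`).

The same steps are available from the shell:

```sh
icgmargin simulate --default --seed 0 --out-dir scratch/phantom
icgmargin segment --video scratch/phantom/video.tiff --seed 0 --out-dir scratch/seg
icgmargin optics attenuation 1000 52       # -> 12.84 dB
```

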