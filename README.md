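# kisstrace

Quantitative image analysis of transient "kissing" contacts between protein
condensates and RNA transcriptional bursts in fluorescence microscopy — with
a synthetic-microscopy generator that provides ground truth for every stage.

## The problem

Retroviral Gag polyproteins form biomolecular condensates that enter the
nucleus and transiently co-localize with nascent unspliced viral RNA (USvRNA)
at transcriptional burst sites, plausibly selecting genomes for packaging
co-transcriptionally. Characterising this interaction from two-channel
live-cell movies (~1 frame/s, minutes-long) and fixed-cell 3D z-stacks
requires a chain of quantitative steps:

* **detection & localization** — fluorescent foci found as scale-normalised
  Laplacian-of-Gaussian maxima with intensity-weighted subpixel centres
  (the contact threshold is only 2–3 pixels, so subpixel accuracy matters);
* **tracking** — per-frame optimal-assignment linking of the few objects in
  these movies, with gap bridging flagged for exclusion from statistics;
* **kissing dynamics** — the centre-to-centre distance trace d(t) between a
  condensate and the burst; a *kissing episode* is a maximal run of frames
  with d ≤ 0.25 µm (the optical resolution limit), and the peak-to-valley
  transit time measures how fast a separated condensate (d > 0.25 µm) dips
  back to contact;
* **intensity correlation** — Pearson r between the condensate and RNA
  intensity series (contacts that transfer material give r < 0);
* **co-localization** — object-based (nearest-centre distance ≤ 0.25 µm,
  per-cell fractions, mean ± SEM) and signal-based (voxelwise AND of
  per-channel exceedance, the "white channel"), including three-way overlap
  with a nascent-RNA channel;
* **nuclear-rim geometry** — 3D distances from foci to the nuclear boundary
  (segmented from a nuclear stain) with anisotropic voxels, within-1 µm
  fractions, nearest-condensate-to-burst distances, and a Welch t test of
  near-versus-far condensate brightness.

The transcriptional burst is defined operationally as the brightest RNA
focus per nucleus (argmax of sum intensity, ties broken by size then label).

Because the raw microscopy of such studies is rarely deposited, the package
includes a first-class simulator: a stationary burst with a condensate
tethered to it by an Ornstein–Uhlenbeck walk (per-axis stationary SD σ,
relaxation time τ; update x' = c + e^{−Δt/τ}(x − c) + σ√(1 − e^{−2Δt/τ}) ξ),
contact-gated intensity exchange that produces anti-correlated traces, 2D/3D
Gaussian-PSF rendering with Poisson and Gaussian noise, and ellipsoidal
nuclei with foci placed at exact analytic boundary distances. Every run
records a ground-truth ledger, so every pipeline stage is tested by
parameter recovery.

## Worked example

```python
from kisstrace import LiveSimConfig, simulate_live_movie
from kisstrace.config import PipelineConfig, tether_sd_for_contact_fraction
from kisstrace.pipeline import run_live_pipeline

cfg = LiveSimConfig(
    n_frames=300,                                           # ~5 min at 1.04 s/frame
    tether_sd_um=tether_sd_for_contact_fraction(0.25, 0.30),  # 30% contact occupancy
    exchange_rate=0.02, intensity_noise_sd=20.0, rng_seed=42,
)
stack, truth = simulate_live_movie(cfg)
report = run_live_pipeline(stack, PipelineConfig())
```

prints (via the snippet in `scripts/` or your own formatting):

```
true contact fraction:     0.353
detected kissing fraction: 0.353
episodes detected:         48
total kissing time:        110.2 s
intensity correlation r:   -0.998 (p = 6.70e-290)
median approach transit:   2.1 s
```

The detected kissing-frame fraction reproduces the simulator's true contact
occupancy to three decimals on this noiseless movie; the strongly negative r
reflects the contact-gated transfer of intensity from the RNA to the protein
channel; the ~2 s median peak-to-valley transit shows how quickly the
tethered condensate returns to contact.

The same chains run from the shell:

```bash
kisstrace simulate live --seed 42 --out sim/
kisstrace run-live sim/movie.tif --out results/
kisstrace simulate fixed --seed 7 --out simf/
kisstrace run-fixed simf/volume.tif --out resultsf/
```

Movies and volumes travel as TIFF with a JSON sidecar carrying pixel
spacing, frame interval and channel names; reports are CSV/JSON (and a
distance-trace PNG).

## Layout

- `src/kisstrace/simulate.py` — synthetic movies/volumes with ground truth
- `src/kisstrace/detect.py` — LoG detection, subpixel centres, nuclear
  segmentation, burst identification
- `src/kisstrace/track.py` — optimal-assignment linking, gap filling
- `src/kisstrace/kissing.py` — distance traces, episodes, approach times,
  Pearson correlation
- `src/kisstrace/coloc.py` — object- and signal-based co-localization
- `src/kisstrace/rim.py` — boundary distances, within-cutoff fractions,
  near/far test, robust outlier flagging
- `src/kisstrace/pipeline.py`, `cli.py` — end-to-end orchestration
- `docs/methods.md` — models, parameters, numerical choices, limitations
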