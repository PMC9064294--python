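# edequant

Quantification pipeline for live-cell fluorescence microscopy of budding
yeast endocytosis and protein condensates. It implements, as tested and
reusable code, the measurements used to characterise condensates formed by
the early endocytic scaffold Ede1 (the yeast Eps15): FRAP recovery
analysis for bleached structures, endocytic patch density and lifetime
from detection and tracking, per-cell cytosolic vs cellular intensity
(the readout of concentration buffering by phase separation), condensate
classification, and two-channel colocalization — together with a
synthetic-movie simulator with exact ground truth, so every estimator is
verifiable without access to raw microscopy.

It is written for microscopists and image analysts who need these
measurements reproducible end to end: from a TIFF movie (or a simulated
one) to fitted parameters and per-cell tables.

## The models at the core

**FRAP.** A bleached region recovers as a single exponential,
`value(t) = M·(1 − exp(−ln2·t/τ½))`, with mobile fraction `M` and
half-time `τ½`. Two protocols are implemented: the *condensate protocol*
(background/cell/structure ROIs, ratio correction for acquisition
bleaching, 0–1 double normalization, per-trace alignment, averaging, fit)
and the *endocytic-site TIRF protocol* (3-pixel circular ROI traces from
background-subtracted movies, raw 0–1 normalization, reference-channel
event selection).

**Patch statistics.** Diffraction-limited patches are detected with a
difference-of-Gaussians band-pass and MAD-based threshold, localized to
sub-pixel precision, and linked into trajectories by exact optimal
assignment between frames. Density uses the spherical-cell approximation
`S = 4A` (membrane surface = 4× projected area), so density = `N/(4A)`
for single unbudded cells; lifetime = frames spanned × frame interval,
with boundary-censored tracks excluded. Conditions are compared by
replicate means (grand mean = mean of per-dataset means, change reported
between grand means).

**Buffering.** Above a critical concentration, extra expression goes into
condensates rather than the cytosol: the mean intensity of small cytosolic
regions saturates while the whole-cell mean keeps rising. The package
measures both per cell, with seeded, exclusion-aware sampling of
cytosolic boxes.

See `docs/methods.md` for assumptions, parameters, and limitations.

## Worked example

The numbered scripts under `analysis/` run the complete studies on
simulated data and write tables under `results/`. For example:

```sh
$ python analysis/02_frap_condensates.py --seed 1
generated with tau_half=22.0 s, M=63%
recovered tau_half=21.49 s, M=63.6% from n=36 events (SSE 0.0161)
```

Thirty-six bleach events were simulated with the reference condensate
parameters (half-time 22 s, mobile fraction 63%, bleach depth 0.8,
Gaussian noise of sd 0.05 on the normalized scale, plus whole-cell
acquisition bleaching), pushed through the full condensate protocol, and
the averaged curve was fitted: the recovered half-time is within 2.3% and
the mobile fraction within 0.6 percentage points of the generating truth.
The other drivers follow the same pattern:

```sh
$ python analysis/04_patch_density_lifetime.py --seed 1
density: 0.0465 um^-2 (truth 0.0450), recall 0.960, precision 0.999, ...
mean lifetime: 92.3 s (configured 90 s, n=903 uncensored tracks)
programmed 46% density reduction measured as 45.0%
```

Library use mirrors the scripts:

```python
from edequant.simulate import SimulationConfig, simulate_movie
from edequant.pipeline import run_pipeline

stack, truth = simulate_movie(SimulationConfig(n_cells=4, n_frames=60,
                                               rng_seed=1))
results = run_pipeline({"simulate": {"n_cells": 4, "n_frames": 60},
                        "rng_seed": 1, "output_dir": "results/run"})
```

## Layout

    src/edequant/       library: simulate, preprocess, frap, patches,
                        cellquant, studies, io, pipeline
    analysis/           numbered narrative drivers (01…06)
    tests/              pytest suite, including end-to-end closed loops
    scripts/            acceptance.py (reproduction script)
    docs/methods.md     models, parameters, design choices, limitations
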