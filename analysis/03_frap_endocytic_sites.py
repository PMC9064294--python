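"""Endocytic-site FRAP closed loop: recover tau_half = 7.8 s and M = 91%.

Simulates 14 single-patch TIRF movies whose amplitudes follow the reference
endocytic-site recovery, extracts 3-pixel circular ROI traces, applies the
raw 0-1 normalization (the protocol makes no background or bleaching
corrections beyond the pre-subtracted movie), averages and fits.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from edequant.frap import (average_aligned_traces, detect_bleach_frame,
                           extract_patch_traces, fit_recovery,
                           normalize_patch_trace, write_fits_csv)
from edequant.simulate import simulate_frap_patch_movies
from edequant.studies import PATCH_FRAP

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

rng = np.random.default_rng([args.seed, 2])
movies, truth = simulate_frap_patch_movies(PATCH_FRAP, 0.05, 14, rng)
normalized = []
for stack, centroid in movies:
    (tr,) = extract_patch_traces(stack, [centroid], frame_interval=0.5)
    tr.bleach_index = detect_bleach_frame(tr)
    normalized.append(normalize_patch_trace(tr))
avg = average_aligned_traces(normalized)
fit = fit_recovery(avg)

pd.DataFrame({"time_s": avg.time_rel, "value": avg.value, "sd": avg.sd,
              "n": avg.n_per_point}).to_csv(
    args.out / "frap_site_average.csv", index=False)
write_fits_csv([fit], args.out / "frap_site_fit.csv", labels=["site"])

g = truth.frap
print(f"generated with tau_half={g.half_time_s} s, M={g.mobile_fraction:.0%}")
print(f"recovered tau_half={fit.half_time_s:.2f} s, "
      f"M={fit.mobile_fraction:.1%} from n={fit.n_traces_averaged} events")
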