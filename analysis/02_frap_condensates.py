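"""Condensate FRAP closed loop: recover tau_half = 22 s and M = 63%.

Simulates 36 bleach events whose generating parameters equal the reference
condensate fit, runs the condensate protocol (ratio correction against the
whole-cell channel, 0-1 double normalization, bleach-time alignment,
averaging, single-exponential fit), and writes the averaged recovery curve
and the fit.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from edequant.frap import (average_aligned_traces, detect_bleach_frame,
                           normalize_condensate_trace, fit_recovery,
                           write_fits_csv)
from edequant.simulate import simulate_frap_experiment
from edequant.studies import CONDENSATE_FRAP

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

rng = np.random.default_rng([args.seed, 1])
traces, truth = simulate_frap_experiment(CONDENSATE_FRAP, 0.05, 36, rng)
normalized = []
for tr in traces:
    tr.bleach_index = detect_bleach_frame(tr)
    normalized.append(normalize_condensate_trace(tr))
avg = average_aligned_traces(normalized)
fit = fit_recovery(avg)

pd.DataFrame({"time_s": avg.time_rel, "value": avg.value, "sd": avg.sd,
              "n": avg.n_per_point}).to_csv(
    args.out / "frap_condensate_average.csv", index=False)
write_fits_csv([fit], args.out / "frap_condensate_fit.csv",
               labels=["condensate"])

g = truth.frap
print(f"generated with tau_half={g.half_time_s} s, M={g.mobile_fraction:.0%}")
print(f"recovered tau_half={fit.half_time_s:.2f} s, "
      f"M={fit.mobile_fraction:.1%} from n={fit.n_traces_averaged} events "
      f"(SSE {fit.residual_sse:.4f})")
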