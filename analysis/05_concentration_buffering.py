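"""Concentration buffering: cytosolic intensity saturates, cellular rises.

Simulates an expression series in which the cytosolic pool is capped at a
saturation level and the excess is deposited into condensates, then
measures both readouts per cell: the mean over the whole masked cell and
the mean over small cytosolic boxes sampled away from bright structures.
"""

import argparse
from pathlib import Path

import pandas as pd

from edequant.studies import buffering_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

out = buffering_study(args.seed)
df = pd.DataFrame({"expression_level": out["levels"],
                   "cytosolic_mean": out["cytosolic_mean"],
                   "cellular_mean": out["cellular_mean"]})
df.to_csv(args.out / "buffering_series.csv", index=False)

print(df.to_string(index=False,
                   float_format=lambda v: f"{v:8.2f}"))
print(f"cytosolic flatness past saturation: "
      f"{out['saturated_flatness']:.1%} peak-to-peak; "
      f"cellular mean monotonic: {out['cellular_monotonic']}")
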