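#!/usr/bin/env python
"""Fit the Luedeking-Piret production constants from culture profiles.

Smooths the full-culture viable-cell profile with a degree-6 polynomial,
derives r_x analytically, and fits alpha and beta by (a) the direct rate
regression and (b) matching the Euler-integrated product profile; compares
both against the generating constants.

Writes results/lp_constants.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import chokinetics as ck
from chokinetics.synthetic_data import (
    ExperimentDesign,
    NoiseModel,
    fixture_params_rcho,
    generate_batch_dataset,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parents[1]
                    / "results" / "lp_constants.json")
args = parser.parse_args()
args.out.parent.mkdir(parents=True, exist_ok=True)

params = fixture_params_rcho()
design = ExperimentDesign(cell_line="r-CHO", S0_levels=(4.8,), replicates=3)
data = generate_batch_dataset(design, params, NoiseModel(seed=args.seed))

report = {"truth": {"alpha": params.alpha, "beta": params.beta}}
for s in data:
    t = s.time
    px = ck.fit_polynomial_window(s, "X", 6)
    r_x = ck.differentiate(px, t)
    X_smooth = np.maximum(px(t), 0.0)

    pp = ck.fit_polynomial_window(s, "P", 6)
    direct = ck.fit_lp_direct(ck.differentiate(pp, t), r_x, X_smooth)
    integral = ck.fit_lp_integral(t, s.P, s.X, dt=0.1)

    report[f"rep{s.replicate}"] = {
        "direct": {"alpha": {"value": direct["alpha"], "units": "ug/cell"},
                   "beta": {"value": direct["beta"], "units": "ug/cell/h"},
                   "r_squared": direct.r_squared},
        "integral": {"alpha": {"value": integral["alpha"], "units": "ug/cell"},
                     "beta": {"value": integral["beta"], "units": "ug/cell/h"},
                     "r_squared": integral.r_squared},
    }
    print(f"rep{s.replicate}: direct alpha {direct['alpha']:.3g}, "
          f"beta {direct['beta']:.3g} | integral alpha {integral['alpha']:.3g}, "
          f"beta {integral['beta']:.3g} "
          f"(truth {params.alpha:.3g}, {params.beta:.3g})")

# pooling replicates reduces the measurement noise that makes alpha hard to
# pin down from any single culture (beta, which dominates the titer, is
# well determined either way)
t = data[0].time
X_bar = np.mean([s.X for s in data], axis=0)
P_bar = np.mean([s.P for s in data], axis=0)
pooled = ck.fit_lp_integral(t, P_bar, X_bar, dt=0.1)
report["pooled"] = {
    "alpha": {"value": pooled["alpha"], "units": "ug/cell"},
    "beta": {"value": pooled["beta"], "units": "ug/cell/h"},
    "r_squared": pooled.r_squared,
}
print(f"pooled (3 reps): alpha {pooled['alpha']:.3g}, beta {pooled['beta']:.3g}; "
      "alpha is weakly identified from noisy single-condition titers — "
      "beta carries most of the product signal")

args.out.write_text(json.dumps(report, indent=2) + "\n")
print(f"wrote {args.out}")
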