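#!/usr/bin/env python
"""Generate the synthetic batch and fed-batch culture datasets.

Emulates the shake-flask study design: r-CHO and n-CHO cultures at 33 C,
initial glucose 4.8/3.6/2.4/1.2 g/L, triplicates, daily sampling, 7-day
(r-CHO) / 10-day (n-CHO) duration, plus one 20-day fed-batch bioreactor
run with five 10%-volume feeds and a day-7 shift to 31 C.

Writes results/data/*.csv.
"""

import argparse
from pathlib import Path

import chokinetics as ck
from chokinetics.synthetic_data import (
    ExperimentDesign,
    NoiseModel,
    default_fedbatch_schedule,
    fixture_params_rcho,
    generate_batch_dataset,
    generate_fedbatch_dataset,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--outdir", type=Path,
                    default=Path(__file__).resolve().parents[1] / "results" / "data")
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

registry = ck.default_registry()

# r-CHO batches: registry growth/production constants plus the death,
# maintenance, and lactate scaffolding that reproduces the observed
# post-peak decline and day-6 glucose depletion
rcho_design = ExperimentDesign(cell_line="r-CHO")
rcho_data = generate_batch_dataset(
    rcho_design, fixture_params_rcho(), NoiseModel(seed=args.seed)
)
ck.write_timeseries(rcho_data, args.outdir / "batch_rcho_33C.csv")

# n-CHO batches: no production, longer duration, dilution-dependent lag
ncho_params = registry.get("n-CHO", 33.0, "table2").with_(
    k_d=0.01, m_s=3e-9, y_lac_x=1.2e-7, q_lac_cons=0.01
)
ncho_design = ExperimentDesign(cell_line="n-CHO")
ncho_data = generate_batch_dataset(
    ncho_design, ncho_params, NoiseModel(seed=args.seed + 1)
)
ck.write_timeseries(ncho_data, args.outdir / "batch_ncho_33C.csv")

# fed-batch bioreactor run
feeds, shifts = default_fedbatch_schedule(V0=1000.0)
fb = generate_fedbatch_dataset(
    ExperimentDesign(cell_line="r-CHO"), registry, feeds, shifts,
    NoiseModel(seed=args.seed + 2),
)
ck.write_timeseries([fb], args.outdir / "fedbatch_rcho.csv")

n_rows = sum(s.n_samples for s in rcho_data + ncho_data) + fb.n_samples
print(f"wrote {len(rcho_data)} r-CHO series, {len(ncho_data)} n-CHO series, "
      f"1 fed-batch series ({n_rows} samples) to {args.outdir}")
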