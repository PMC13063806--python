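#!/usr/bin/env python
"""Lateral diffusion recovery: MSD fitting against known generator truth.

Simulates Brownian bilayers with the literature diffusion coefficients
(Ld-like 1.2e-7 cm^2/s, Lo-like 1.2e-8 cm^2/s), unwraps the periodic
trajectories, and fits MSD = 4 D tau over the 10-200 ns lag window.  The
recovered per-species coefficients should match truth within a few
percent and keep their factor-of-ten separation.
"""

from pathlib import Path

import pandas as pd

from memraft import io as mio
from memraft import validation as v

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

r = v.diffusion_recovery(seed=1, n_seeds=5)
table = pd.DataFrame(
    [
        {
            "species": "fast (Ld-like)",
            "d_true_cm2_s": 1.2e-7,
            "d_recovered_cm2_s": r["d_fast_recovered_cm2_s"],
            "median_rel_err_pct": round(100 * r["median_rel_err_fast"], 2),
        },
        {
            "species": "slow (Lo-like)",
            "d_true_cm2_s": 1.2e-8,
            "d_recovered_cm2_s": r["d_slow_recovered_cm2_s"],
            "median_rel_err_pct": round(100 * r["median_rel_err_slow"], 2),
        },
    ]
)
mio.write_results(RESULTS / "diffusion_recovery.tsv", table)
print(table.to_string(index=False))
print(
    f"\nrecovered fast/slow ratio = {r['median_ratio']:.2f} "
    f"(truth 10.0) over {r['n_seeds']} seeds x {r['n_frames']} frames"
)
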