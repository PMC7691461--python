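#!/usr/bin/env python
"""Outlier-window detection with a coalescent simulation null.

Flags high-differentiation (top-1% FST with negative Tajima's D) and
low-differentiation (FST < 0.15) windows for the focal N-S pair, attaches
Monte-Carlo p-values from 2,000 null simulations under the fitted demography
with Benjamini-Hochberg FDR per tail, and contrasts the outlier windows
against the genomic background with Wilcoxon rank-sum tests on dxy, pi and
Tajima's D.  Requires results/sim/ with a scan table.
"""

import numpy as np
import pandas as pd

from pathlib import Path

from aspenscan.demography import scaled_model, table1_model
from aspenscan import pipeline
from aspenscan.selection_scan import rank_sum_compare

SIM = str(Path(__file__).resolve().parents[1] / "results" / "sim")
SCALE = 50.0  # must match 01_simulate_data.py


def main() -> None:
    null_model = scaled_model(table1_model(), SCALE)
    res = pipeline.run_outliers(
        SIM, f"{SIM}/scan.tsv", null_model, {"N": 8, "C": 8, "S": 8},
        n_sims=2_000, seed=41,
    )
    out = pd.read_csv(res["outliers"], sep="\t")
    scan = pd.read_csv(f"{SIM}/scan.tsv", sep="\t")
    print(f"windows: {len(out)}; high_diff flagged: {int(out.high_diff.sum())}; "
          f"low_diff flagged: {int(out.low_diff.sum())}")
    print(f"FDR<1% candidates: {int(out.candidate_high.sum())} high, "
          f"{int(out.candidate_low.sum())} low")

    hi = out["high_diff"].to_numpy()
    bg = ~hi & ~out["low_diff"].to_numpy()
    if hi.sum() >= 3:
        for col in ("dxy_N_S", "pi_N", "pi_S", "tajD_N", "tajD_S"):
            x = scan.loc[hi, col].to_numpy(float)
            y = scan.loc[bg, col].to_numpy(float)
            u, p, direction = rank_sum_compare(x, y)
            print(f"rank-sum {col}: outliers {direction} than background "
                  f"(U={u:.0f}, p={p:.3g})")


if __name__ == "__main__":
    main()
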