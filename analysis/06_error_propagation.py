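#!/usr/bin/env python
"""How much do local-ancestry-caller errors bias asF?

Corrupts true ancestry tracts with a 90%-accuracy confusion matrix in
0.2 cM windows, re-estimates the Indigenous asF across a MAF grid, and
compares simulated means against the closed-form expectation
E[asF_x] = sum_y pi_y C[y,x] f_y / sum_y pi_y C[y,x].
"""

import os

import numpy as np
import pandas as pd

from admixfreq.frequencies import expected_asf_under_confusion
from admixfreq.pipeline import default_confusion_matrix
from admixfreq.simulate import SimulationConfig, asf_error_experiment

HERE = os.path.dirname(os.path.abspath(__file__))
ROOT = os.path.dirname(HERE)
RESULTS = os.path.join(ROOT, "results")

MAF_GRID = [0.02, 0.05, 0.1, 0.25, 0.5]
OTHER_FREQS = np.array([0.6, 0.4, 0.5, 0.0])  # AFR, EUR, EAS, (IND swept)


def main() -> None:
    cm = default_confusion_matrix(accuracy=0.90)
    cfg = SimulationConfig(n_individuals=1000, n_sites=len(MAF_GRID), seed=29)
    table = asf_error_experiment(cfg, cm, MAF_GRID, n_replicates=20, seed=29,
                                 other_freqs=OTHER_FREQS)
    pi = cfg.proportions_by_stratum[0]
    rows = []
    for _, r in table[(table["ancestry"] == "IND")].iterrows():
        f = OTHER_FREQS.copy()
        f[3] = r["maf"]
        expect = (expected_asf_under_confusion(pi, cm, f, "IND")
                  if r["call_type"] == "corrupted" else r["true_f"])
        rows.append({**r, "expected": expect,
                     "bias": r["mean_est_f"] - r["true_f"]})
    out_df = pd.DataFrame(rows)
    out = os.path.join(RESULTS, "06_asf_error_sim.tsv")
    out_df.to_csv(out, sep="\t", index=False, float_format="%.5f")

    corrupted = out_df[out_df["call_type"] == "corrupted"]
    props = "/".join(f"{x:.2f}" for x in pi)
    print("Indigenous asF under 90%-accuracy ancestry calls "
          f"(proportions AFR/EUR/EAS/IND = {props}):")
    print(corrupted[["maf", "mean_est_f", "expected", "bias"]]
          .to_string(index=False))
    print(f"\nmax |bias| across the grid: {corrupted['bias'].abs().max():.4f} "
          "- caller noise shifts asF toward the admixture-weighted mean, "
          "and the simulation tracks the analytic expectation.")
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
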