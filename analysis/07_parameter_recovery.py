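#!/usr/bin/env python
"""Parameter-recovery study on synthetic observation tables.

Generates synthetic datasets from the bundled parameters at 8 log-spaced
nutrient levels on [0.25, 41] uM (bracketing the smallest half-saturation
constant being recovered), then re-fits the stage-1 growth and import laws
from a deliberately displaced start (30-40% off), noise-free and at 5%
multiplicative noise over 20 seeds.

Finding: noise-free recovery is within ~3.5% for every stage-1 parameter;
at 5% noise the worst per-parameter median error is ~14% (WT growth
half-saturation, the least identifiable constant at 0.13 uM).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from yeastiron.fitting import fit_c1
from yeastiron.params import canonical_parameters
from yeastiron.synthetic import (
    SyntheticConfig, effective_c1_truth, generate_observations, noiseless_truth,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    base = {s: canonical_parameters(s) for s in ("WT", "DD")}
    n_grid = tuple(float(x) for x in np.round(np.logspace(np.log10(0.25), np.log10(41.0), 8), 3))
    start = {s: p.replace(alpha_max=p.alpha_max * 1.3, K_alpha=p.K_alpha * 0.7,
                          R_cell_max=p.R_cell_max * 1.4, K_N=p.K_N * 0.8, sens=1.3)
             for s, p in base.items()}
    cfg0 = SyntheticConfig(true_parameters=base, N_values=n_grid)
    truth, eff = noiseless_truth(cfg0), effective_c1_truth(cfg0)

    def errors(res):
        out = {}
        for s in ("WT", "DD"):
            for name in ("alpha_max", "K_alpha", "R_cell_max"):
                key = name if name == "alpha_max" else f"{name}@{s}"
                out[f"{name}@{s}"] = abs(res.parameters[key] / eff[s][name] - 1.0)
        return out

    rows = []
    recs, _ = generate_observations(cfg0, truth)
    nf = errors(fit_c1(recs, start, init_from_data=True))
    rows += [dict(noise_cv=0.0, seed=-1, parameter=k, rel_err=v) for k, v in nf.items()]
    for k in range(20):
        cfg = SyntheticConfig(true_parameters=base, N_values=n_grid, noise_cv=0.05,
                              seed=(args.seed * 1009 + k) % (2**31))
        r, _ = generate_observations(cfg, truth)
        rows += [dict(noise_cv=0.05, seed=k, parameter=p, rel_err=v)
                 for p, v in errors(fit_c1(r, start, init_from_data=True)).items()]
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "parameter_recovery.csv", index=False)
    print("noise-free max error: %.3f%%" % (100 * max(nf.values())))
    med = df[df.noise_cv == 0.05].groupby("parameter").rel_err.median()
    print("CV=5% median errors (%):")
    print((100 * med).round(1).to_string())
    print(f"wrote {OUT / 'parameter_recovery.csv'}")


if __name__ == "__main__":
    main()
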