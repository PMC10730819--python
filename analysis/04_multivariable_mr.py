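#!/usr/bin/env python
"""Multivariable MR: direct effect of the exposure adjusted for a co-exposure.

Simulates two correlated exposures with true direct effects (0.3, 0.0) on
the outcome and reports the multivariable IVW decomposition with
conditional instrument-strength F statistics.
"""

import argparse

from _common import RESULTS
from mrkit.mvmr import harmonize_mv, mvmr_ivw
from mrkit.simulate import SimConfig, simulate


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()

    sim = simulate(SimConfig(seed=args.seed, J=60, K=2, theta=(0.3, 0.0),
                             se_exposure=0.005, gamma_mean=0.15, gamma_sd=0.05))
    m = harmonize_mv(sim.exposures, sim.outcome,
                     labels=["pm25_like", "co_pollutant"])
    res = mvmr_ivw(m)
    df = res.to_frame()
    out = RESULTS / "mvmr.tsv"
    df.to_csv(out, sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"true direct effects: (0.3, 0.0); heterogeneity Q = {res.heterogeneity_q:.1f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
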