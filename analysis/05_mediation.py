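#!/usr/bin/env python
"""Two-step MR mediation: full study run plus the reference-table arithmetic.

Part 1 drives the complete pipeline (instrument selection, univariable
screen, sensitivity, mediation with gating) over the synthetic bundle and
writes the study report.  Part 2 recomputes the published
PM2.5 -> mediator -> longevity mediation effects and mediated proportions
from the printed direct effects A and B via the product-of-coefficients
method.  Requires the bundle from 01_simulate_cohorts.py.
"""

import argparse

import pandas as pd

from _common import MEDIATORS, OUTCOMES, RESULTS, bundle_paths
from mrkit.datasets import longevity_mediation_coefficients
from mrkit.mediation import indirect_effect, mediated_proportion
from mrkit.pipeline import RunConfig, run_study


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()

    paths = bundle_paths()
    cfg = RunConfig(
        exposure_path=paths["exposure"],
        outcome_paths={o: paths[o] for o in OUTCOMES},
        mediator_paths={m: paths[m] for m in MEDIATORS},
        ld_path=paths["__ld__"],
        seed=args.seed,
        presso_n_sim=1000,
    )
    report = run_study(cfg)
    report.write(RESULTS / "study")
    print(f"gated mediators (step-1 IVW p < 0.05): "
          f"{report.provenance['gated_mediators']}")
    print(report.mediation[["mediator", "outcome", "indirect_beta",
                            "proportion"]].to_string(index=False))

    # reference arithmetic: recompute each published mediation effect
    table = longevity_mediation_coefficients()
    rows = []
    for _, r in table.iterrows():
        res = indirect_effect(r["a"], r["a_se"], r["b"], r["b_se"])
        prop, (lo, hi) = mediated_proportion(res.beta, r["total"], res.se)
        rows.append({"mediator": r["mediator"], "percentile": r["percentile"],
                     "recomputed_mediation": round(res.beta, 2),
                     "reported_mediation": r["mediation_ref"],
                     "recomputed_proportion": round(prop, 2),
                     "reported_proportion": r["proportion_ref"]})
    ref = pd.DataFrame(rows)
    out = RESULTS / "reference_mediation_recomputed.tsv"
    ref.to_csv(out, sep="\t", index=False)
    n_match = (ref.recomputed_mediation == ref.reported_mediation).sum()
    print(f"\nreference table: {n_match}/{len(ref)} mediation effects "
          f"reproduced exactly at two decimals")
    print(f"wrote {out} and {RESULTS / 'study'}")


if __name__ == "__main__":
    main()
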