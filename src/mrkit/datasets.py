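"""Bundled worked-example data.

``longevity_mediation_coefficients`` returns the coefficient table from a
published two-sample MR mediation analysis of fine-particulate-matter
(PM2.5) exposure and human longevity (surviving past the cohort 90th or
99th survival percentile).  Per mediator and longevity percentile it gives,
on the log-odds scale:

* ``total`` — total effect of PM2.5 on longevity, with 95% CI;
* ``a``     — direct effect A, PM2.5 -> mediator, with 95% CI;
* ``b``     — direct effect B, mediator -> longevity, with 95% CI;
* reference columns ``mediation_ref`` / ``proportion_ref`` (and CI bounds)
  holding the values reported alongside the inputs, at their printed
  precision, for cross-checking recomputed products.

Standard-error columns are recovered from the CI half-widths (1.96
multiplier).  These rows are the inputs to the worked example in the README
and to ``scripts/acceptance.py``, which re-derive the mediation effects and
mediated proportions from A, B and the total via
:func:`mrkit.mediation.indirect_effect` and
:func:`mrkit.mediation.mediated_proportion`.
"""

from __future__ import annotations

import pandas as pd

_Z = 1.96

# mediator, percentile, total (lo, hi), A (lo, hi), B (lo, hi),
# mediation_ref (lo, hi), pval_ref, proportion_ref (lo, hi)
_ROWS = [
    ("DBP", "90th", -0.57, -2.12, 0.97, -2.65, -3.97, -1.32, -0.068, -0.082, -0.054,
     0.18, 0.083, 0.28, 0.00029, 31.48, 14.44, 48.51),
    ("DBP", "99th", -1.13, -3.55, 1.28, -2.65, -3.97, -1.32, -0.077, -0.099, -0.056,
     0.21, 0.088, 0.32, 0.00060, 28.42, 7.76, 18.09),
    ("hypertension", "90th", -0.57, -2.12, 0.97, 0.081, 0.016, 0.15, -5.01, -6.09, -3.92,
     -0.41, -0.74, -0.070, 0.018, 70.86, 12.23, 100.0),
    ("hypertension", "99th", -1.13, -3.55, 1.28, 0.081, 0.016, 0.15, -5.70, -7.52, -3.87,
     -0.46, -0.86, -0.065, 0.023, 40.86, 5.70, 76.02),
    ("hypercholesterolaemia", "90th", -0.57, -2.12, 0.97, 0.072, 0.0070, 0.14,
     -9.61, -12.95, -6.27, -0.69, -1.36, -0.023, 0.043, 100.0, 3.92, 100.0),
    ("hypercholesterolaemia", "99th", -1.13, -3.55, 1.28, 0.072, 0.0070, 0.14,
     -13.13, -18.87, -7.38, -0.94, -1.89, 0.0029, 0.051, 83.18, 0.0, 100.0),
    ("angina", "90th", -0.57, -2.12, 0.97, 0.045, 0.011, 0.078, -0.36, -0.50, -0.21,
     -0.014, -0.026, -0.0022, 0.020, 2.45, 0.39, 4.50),
    ("angina", "99th", -1.13, -3.55, 1.28, 0.045, 0.011, 0.078, -0.39, -0.58, -0.20,
     -0.017, -0.033, -0.0020, 0.026, 1.53, 0.18, 2.88),
    ("hypothyroidism", "90th", -0.57, -2.12, 0.97, 0.092, 0.060, 0.13, -3.69, -7.27, -0.11,
     -0.34, -0.69, 0.011, 0.058, 59.37, 0.0, 100.0),
    ("hypothyroidism", "99th", -1.13, -3.55, 1.28, 0.092, 0.060, 0.13, -1.48, -7.23, 4.27,
     -0.14, -0.67, 0.40, 0.62, 12.05, 0.0, 59.16),
    ("AD", "90th", -0.57, -2.12, 0.97, 0.48, 0.014, 0.96, -0.29, -0.36, -0.22,
     -0.14, -0.28, -0.00016, 0.05, 24.65, 0.0, 49.27),
    ("AD", "99th", -1.13, -3.55, 1.28, 0.48, 0.014, 0.96, -0.39, -0.50, -0.28,
     -0.19, -0.38, 0.0026, 0.053, 16.61, 0.0, 33.46),
]

_COLUMNS = [
    "mediator", "percentile",
    "total", "total_lo", "total_hi",
    "a", "a_lo", "a_hi",
    "b", "b_lo", "b_hi",
    "mediation_ref", "mediation_ref_lo", "mediation_ref_hi",
    "pval_ref",
    "proportion_ref", "proportion_ref_lo", "proportion_ref_hi",
]


def longevity_mediation_coefficients() -> pd.DataFrame:
    """The PM2.5 -> mediator -> longevity coefficient table (see module docs)."""
    df = pd.DataFrame(_ROWS, columns=_COLUMNS)
    for stem in ("total", "a", "b"):
        df[f"{stem}_se"] = (df[f"{stem}_hi"] - df[f"{stem}_lo"]) / (2 * _Z)
    return df
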