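"""MR-PRESSO: simulation-based detection of horizontally pleiotropic outliers.

Three tests built on leave-one-out IVW residuals:

* **global test** — the observed inverse-variance-weighted residual sum of
  squares (each SNP's residual taken against the IVW fit that excludes it)
  is compared with its parametric null distribution, obtained by redrawing
  outcome effects from N(predicted, se_outcome) and recomputing the RSS.
* **outlier test** — each SNP's weighted squared residual gets an empirical
  p-value against the simulated residuals at that SNP, Bonferroni-corrected
  across SNPs; flagged SNPs are removed and IVW re-run on the remainder.
* **distortion test** — the shift between the raw and outlier-corrected
  estimates is compared with the shifts produced by removing random SNP
  subsets of the same size.

Empirical p-values use the add-one (r+1)/(n+1) convention, so they are never
exactly zero.  All randomness flows from a mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientInstrumentsError, MRKitError
from .estimators import MREstimate, ivw
from .summary_io import HarmonizedSet


@dataclass
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_ids: list
    outlier_pvals: dict
    distortion_pval: float | None
    raw: MREstimate
    corrected: MREstimate
    n_sim: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Per-SNP outlier statistics."""
        return pd.DataFrame(
            {
                "SNP": list(self.outlier_pvals),
                "outlier_p": list(self.outlier_pvals.values()),
                "flagged": [s in self.outlier_ids for s in self.outlier_pvals],
            }
        )


def _loo_residuals(x, y, w):
    """Per-SNP residual y_j - beta_{-j} x_j from leave-one-out IVW fits.

    Supports a matrix of outcome vectors (rows) against a shared x.
    """
    y = np.atleast_2d(y)
    sxx = np.sum(w * x**2)
    sxy = y @ (w * x)
    beta_loo = (sxy[:, None] - (w * x) * y) / (sxx - w * x**2)
    return np.squeeze(y - beta_loo * x)


def presso(
    h: HarmonizedSet,
    n_sim: int = 5000,
    *,
    seed: int,
    outlier_alpha: float = 0.05,
    ivw_mode: str = "auto",
) -> PressoResult:
    """Run the global, outlier and distortion tests and re-estimate IVW on
    the surviving instruments."""
    J = h.n_snps
    if J < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs at least four SNPs")
    if n_sim < 1000:
        raise ConfigurationError("n_sim must be at least 1000")

    x = h.beta_exposure
    w = 1.0 / h.se_outcome**2
    rng = np.random.default_rng(seed)

    resid_obs = _loo_residuals(x, h.beta_outcome, w)
    contrib_obs = w * resid_obs**2
    rss_obs = float(np.sum(contrib_obs))

    # Parametric null: outcome effects redrawn around the leave-one-out fits.
    sxx = np.sum(w * x**2)
    sxy = np.sum(w * x * h.beta_outcome)
    beta_loo = (sxy - w * x * h.beta_outcome) / (sxx - w * x**2)
    y_sim = rng.normal(beta_loo * x, h.se_outcome, size=(n_sim, J))
    resid_sim = _loo_residuals(x, y_sim, w)
    contrib_sim = w * resid_sim**2
    rss_sim = contrib_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    per_snp_p = (1 + np.sum(contrib_sim >= contrib_obs, axis=0)) / (n_sim + 1)
    flagged = per_snp_p < outlier_alpha / J
    outlier_ids = [s for s, f in zip(h.snp_ids, flagged) if f]
    if len(outlier_ids) == J:
        raise MRKitError("no instruments survive outlier removal")

    raw = ivw(h, mode=ivw_mode)
    keep = [j for j in range(J) if not flagged[j]]
    corrected = ivw(h.subset(keep), mode=ivw_mode)

    distortion_pval = None
    if outlier_ids:
        n_out = len(outlier_ids)
        d_obs = raw.beta - corrected.beta
        n_draw = min(n_sim, 1000)
        d_sim = np.empty(n_draw)
        for i in range(n_draw):
            drop = rng.choice(J, size=n_out, replace=False)
            keep_i = np.setdiff1d(np.arange(J), drop)
            d_sim[i] = raw.beta - ivw(h.subset(keep_i), mode=ivw_mode).beta
        distortion_pval = float((1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_draw + 1))

    return PressoResult(
        global_rss=rss_obs,
        global_pval=global_pval,
        outlier_ids=outlier_ids,
        outlier_pvals=dict(zip(h.snp_ids, per_snp_p.tolist())),
        distortion_pval=distortion_pval,
        raw=raw,
        corrected=corrected,
        n_sim=n_sim,
        seed=seed,
    )
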