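"""Multivariable MR: direct effects of several exposures in one model.

The multivariable IVW estimate is the weighted-least-squares fit of the SNP
outcome effects on the J x K matrix of SNP exposure effects, no intercept,
weights 1/se_outcome^2.  Each coefficient is the direct effect of that
exposure conditional on the others.  Standard errors carry the same
multiplicative overdispersion floor max(1, sigma) as univariable IVW, so
K = 1 reduces exactly to the univariable estimator.

Instrument strength per exposure is summarised by a conditional F statistic:
each exposure's SNP effects are regressed (inverse-variance weighted) on the
co-exposures' effects and the mean squared residual z-score is reported.
Values below 10 are flagged, never auto-dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CollinearityError, HarmonizationError, InsufficientInstrumentsError
from .estimators import _finish, MREstimate
from .summary_io import HarmonizedSet, harmonize


@dataclass
class MVHarmonizedSet:
    """Per-SNP effects on K exposures and one outcome, on a shared
    effect-allele convention."""

    snp_ids: list
    exposure_labels: list
    beta_exposures: np.ndarray  # (J, K)
    se_exposures: np.ndarray  # (J, K)
    beta_outcome: np.ndarray
    se_outcome: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return self.beta_exposures.shape[1]


@dataclass
class MVMRResult:
    estimates: list  # MREstimate per exposure, labels in exposure order
    exposure_labels: list
    conditional_f: dict
    heterogeneity_q: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.exposure_labels,
                "beta": [e.beta for e in self.estimates],
                "se": [e.se for e in self.estimates],
                "ci_low": [e.ci_low for e in self.estimates],
                "ci_high": [e.ci_high for e in self.estimates],
                "pval": [e.pval for e in self.estimates],
                "conditional_F": [self.conditional_f[l] for l in self.exposure_labels],
            }
        )


def harmonize_mv(exposure_lists, outcome, labels=None, snp_ids=None) -> MVHarmonizedSet:
    """Harmonize several exposure studies and one outcome study onto the
    first exposure's allele convention.

    ``exposure_lists`` is a sequence of record lists; ``snp_ids`` optionally
    restricts the instrument pool (e.g. the union of each exposure's selected
    instruments).  Only SNPs present and allele-compatible in every study are
    retained.
    """
    K = len(exposure_lists)
    if K < 1:
        raise HarmonizationError("need at least one exposure")
    labels = list(labels) if labels else [f"exposure_{k+1}" for k in range(K)]

    # Align each study (including the reference itself) against exposure 0.
    ref = exposure_lists[0]
    if snp_ids is not None:
        pool = set(snp_ids)
        ref = [r for r in ref if r.snp_id in pool]
    aligned = [harmonize(ref, other) for other in list(exposure_lists) + [outcome]]
    shared = set(aligned[0].snp_ids)
    for h in aligned[1:]:
        shared &= set(h.snp_ids)
    if not shared:
        raise HarmonizationError("no shared instruments across all traits")
    order = [s for s in aligned[0].snp_ids if s in shared]

    def pick(h: HarmonizedSet):
        idx = {s: j for j, s in enumerate(h.snp_ids)}
        rows = [idx[s] for s in order]
        return h.beta_outcome[rows], h.se_outcome[rows]

    bx = np.column_stack([pick(aligned[k])[0] for k in range(K)])
    sx = np.column_stack([pick(aligned[k])[1] for k in range(K)])
    by, sy = pick(aligned[K])
    return MVHarmonizedSet(
        snp_ids=order,
        exposure_labels=labels,
        beta_exposures=bx,
        se_exposures=sx,
        beta_outcome=by,
        se_outcome=sy,
    )


def _check_rank(X, w, labels):
    Xw = X * np.sqrt(w)[:, None]
    if np.linalg.matrix_rank(Xw) < X.shape[1]:
        K = X.shape[1]
        culprits = []
        for a in range(K):
            for b in range(a + 1, K):
                c = np.corrcoef(X[:, a], X[:, b])[0, 1]
                if abs(c) > 1 - 1e-10:
                    culprits.append((labels[a], labels[b]))
        detail = f" (collinear pairs: {culprits})" if culprits else ""
        raise CollinearityError(f"exposure effect matrix is rank deficient{detail}")


def mvmr_ivw(m: MVHarmonizedSet) -> MVMRResult:
    """Multivariable IVW direct effects with overdispersion-scaled SEs."""
    J, K = m.beta_exposures.shape
    if J <= K:
        raise InsufficientInstrumentsError(
            f"under-identified: J={J} instruments for K={K} exposures"
        )
    X = m.beta_exposures
    y = m.beta_outcome
    w = 1.0 / m.se_outcome**2
    _check_rank(X, w, m.exposure_labels)

    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    coefs = cov @ (XtW @ y)
    resid = y - X @ coefs
    q = float(np.sum(w * resid**2))
    sigma2 = q / (J - K)
    infl = max(1.0, np.sqrt(sigma2))
    ses = np.sqrt(np.diag(cov)) * infl

    estimates = [
        _finish("mvmr_ivw", coefs[k], ses[k], J) for k in range(K)
    ]

    cond_f = {}
    for k in range(K):
        wk = 1.0 / m.se_exposures[:, k] ** 2
        if K == 1:
            delta = X[:, 0]
        else:
            others = np.delete(X, k, axis=1)
            OtW = others.T * wk
            gamma = np.linalg.solve(OtW @ others, OtW @ X[:, k])
            delta = X[:, k] - others @ gamma
        cond_f[m.exposure_labels[k]] = float(np.mean((delta / m.se_exposures[:, k]) ** 2))

    return MVMRResult(
        estimates=estimates,
        exposure_labels=list(m.exposure_labels),
        conditional_f=cond_f,
        heterogeneity_q=q,
    )
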