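"""Univariable two-sample MR estimators.

All estimators consume a :class:`~mrkit.summary_io.HarmonizedSet` of per-SNP
exposure and outcome effects.  The inverse-variance-weighted (IVW) estimate
is the weighted-least-squares slope of outcome on exposure effects through
the origin with weights 1/se_outcome^2, identical to the inverse-variance
weighted mean of per-SNP Wald ratios.  The multiplicative random-effects
variant inflates the fixed-effect standard error by max(1, residual scale),
so it is never narrower than the fixed-effect interval.  MR-Egger frees the
intercept (average directional pleiotropy) and draws its inference from a t
distribution with J-2 degrees of freedom.  The weighted median takes the
50% point of the inverse-variance-weighted empirical distribution of Wald
ratios, with a seeded parametric bootstrap for its standard error.

Confidence intervals use the fixed 1.96 normal multiplier throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import (
    CollinearityError,
    ConfigurationError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from .summary_io import HarmonizedSet

Z95 = 1.96


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with its uncertainty and provenance."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    or_value: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    scale: str = "beta"


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope plus the directional-pleiotropy intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def to_odds_ratio(beta, se):
    """Exponentiate a log-odds effect: (OR, 95% CI low, 95% CI high)."""
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z95 * se)),
        float(np.exp(beta + Z95 * se)),
    )


def _finish(method, beta, se, n_snps, pval=None, df=None) -> MREstimate:
    beta, se = float(beta), float(se)
    if pval is None:
        z = beta / se if se > 0 else np.inf * np.sign(beta)
        if df is not None:
            pval = float(2 * stats.t.sf(abs(z), df))
        else:
            pval = float(2 * stats.norm.sf(abs(z)))
    orv, orl, orh = to_odds_ratio(beta, se)
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=pval,
        n_snps=int(n_snps),
        or_value=orv,
        or_ci_low=orl,
        or_ci_high=orh,
    )


def wald_ratio(beta_out, se_out, beta_exp) -> MREstimate:
    """Single-SNP causal estimate beta_out/beta_exp with first-order SE."""
    if beta_exp == 0:
        raise DegenerateInstrumentError("Wald ratio undefined for beta_exposure = 0")
    return _finish("wald", beta_out / beta_exp, se_out / abs(beta_exp), 1)


def _wls(x, y, w, intercept: bool):
    """Weighted least squares; returns (coefs, cov_unscaled, sigma2, df).

    ``cov_unscaled`` is (X'WX)^-1; ``sigma2`` the weighted residual variance
    with df = J - n_params.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    XtW = X.T * w
    A = XtW @ X
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        raise CollinearityError("zero variance in beta_exposure") from None
    coefs = cov @ (XtW @ y)
    resid = y - X @ coefs
    df = len(y) - X.shape[1]
    sigma2 = float(np.sum(w * resid**2) / df) if df > 0 else float("nan")
    return coefs, cov, sigma2, df


def ivw(h: HarmonizedSet, mode: str = "auto") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``mode``: ``fixed``, ``mre`` (multiplicative random effects) or ``auto``
    (mre when J >= 4, fixed otherwise).  The mre standard error is the fixed
    one scaled by max(1, sqrt(weighted residual variance)).
    """
    if mode not in ("auto", "fixed", "mre"):
        raise ConfigurationError(f"unknown IVW mode {mode!r}")
    J = h.n_snps
    if J < 1:
        raise InsufficientInstrumentsError("IVW needs at least one SNP")
    if np.all(h.beta_exposure == 0):
        raise DegenerateInstrumentError("all beta_exposure are zero")
    if mode == "auto":
        mode = "mre" if J >= 4 else "fixed"
    if mode == "mre" and J < 2:
        raise InsufficientInstrumentsError("random-effects IVW needs at least two SNPs")

    w = 1.0 / h.se_outcome**2
    coefs, cov, sigma2, _ = _wls(h.beta_exposure, h.beta_outcome, w, intercept=False)
    beta = coefs[0]
    se = float(np.sqrt(cov[0, 0]))
    if mode == "mre":
        se *= max(1.0, np.sqrt(sigma2))
    return _finish(f"ivw_{mode}", beta, se, J)


def _weighted_median_point(ratios, weights):
    """Linear interpolation of the weighted empirical CDF at probability 0.5."""
    order = np.argsort(ratios)
    b = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= cum[0]:
        return float(b[0])
    if 0.5 >= cum[-1]:
        return float(b[-1])
    k = int(np.searchsorted(cum, 0.5, side="right")) - 1
    frac = (0.5 - cum[k]) / (cum[k + 1] - cum[k])
    return float(b[k] + frac * (b[k + 1] - b[k]))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, *, seed: int) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Consistent when instruments carrying at least half the weight are valid.
    The bootstrap redraws per-SNP exposure and outcome effects from their
    Gaussian sampling distributions; the seed is mandatory.
    """
    J = h.n_snps
    if J < 3:
        raise InsufficientInstrumentsError("weighted median needs at least three SNPs")
    if np.any(h.beta_exposure == 0):
        raise DegenerateInstrumentError("beta_exposure = 0 gives an undefined Wald ratio")
    ratios = h.beta_outcome / h.beta_exposure
    weights = h.beta_exposure**2 / h.se_outcome**2  # 1 / var(Wald ratio), first order
    point = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    bx = rng.normal(h.beta_exposure, h.se_exposure, size=(n_boot, J))
    by = rng.normal(h.beta_outcome, h.se_outcome, size=(n_boot, J))
    bx[bx == 0] = np.finfo(float).tiny
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _weighted_median_point(by[i] / bx[i], bx[i] ** 2 / h.se_outcome**2)
    se = float(np.std(boots, ddof=1))
    return _finish("weighted_median", point, se, J)


def mr_egger(h: HarmonizedSet) -> EggerResult:
    """MR-Egger regression: slope = causal effect, intercept = average
    directional pleiotropy.  SNPs are oriented so beta_exposure >= 0; both
    tests use a t distribution with J-2 df and the multiplicative
    overdispersion floor max(1, sigma)."""
    J = h.n_snps
    if J < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least three SNPs")
    sign = np.where(h.beta_exposure < 0, -1.0, 1.0)
    x = h.beta_exposure * sign
    y = h.beta_outcome * sign
    w = 1.0 / h.se_outcome**2

    xbar = np.sum(w * x) / np.sum(w)
    if np.allclose(x, xbar):
        raise CollinearityError("zero variance in beta_exposure; Egger slope unidentified")
    coefs, cov, sigma2, df = _wls(x, y, w, intercept=True)
    infl = max(1.0, np.sqrt(sigma2))
    se_int = float(np.sqrt(cov[0, 0])) * infl
    se_slope = float(np.sqrt(cov[1, 1])) * infl
    slope = _finish("egger_slope", coefs[1], se_slope, J, df=df)
    int_p = float(2 * stats.t.sf(abs(coefs[0] / se_int), df))
    return EggerResult(
        slope=slope,
        intercept=float(coefs[0]),
        intercept_se=se_int,
        intercept_pval=int_p,
    )


def with_scale(est: MREstimate, scale: str) -> MREstimate:
    """Tag an estimate with an explicit scale label ('beta' or 'or')."""
    return replace(est, scale=scale)
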