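"""Two-step MR mediation: product of coefficients with delta-method SE.

Step 1 estimates the exposure->mediator effect (A) with the exposure's
instruments; step 2 estimates the mediator->outcome effect (B) with the
mediator's own instruments.  The indirect (mediation) effect is the product
A*B; its standard error is the first-order delta-method (Sobel) form

    se = sqrt(A^2 * se_B^2 + B^2 * se_A^2)

and the mediated proportion is the indirect effect as a percentage of the
total exposure->outcome effect, reported as a magnitude and clipped to
[0, 100].  When the indirect and total effects disagree in sign the result
carries an ``inconsistent`` flag (the magnitude convention still applies).
All binary-trait effects must enter on the log-odds scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .errors import MRKitError, ScaleError
from .estimators import MREstimate, Z95


class IndirectEffect(NamedTuple):
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float


@dataclass
class MediationResult:
    """Total, direct and indirect effects with the mediated proportion."""

    total_beta: float
    total_se: float
    a_beta: float
    a_se: float
    b_beta: float
    b_se: float
    indirect_beta: float
    indirect_se: float
    indirect_ci_low: float
    indirect_ci_high: float
    indirect_pval: float
    proportion: float
    proportion_ci_low: float
    proportion_ci_high: float
    inconsistent: bool = False
    provenance: dict | None = None


def indirect_effect(a_beta, a_se, b_beta, b_se) -> IndirectEffect:
    """Product-of-coefficients indirect effect with first-order delta SE."""
    if a_se <= 0 or b_se <= 0:
        raise MRKitError("standard errors must be positive")
    beta = a_beta * b_beta
    se = float(np.sqrt(a_beta**2 * b_se**2 + b_beta**2 * a_se**2))
    if se > 0:
        pval = float(2 * stats.norm.sf(abs(beta) / se))
    else:  # a = b = 0: no evidence either way
        pval = 1.0
    return IndirectEffect(
        beta=float(beta),
        se=se,
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=pval,
    )


def _clip_pct(v):
    return float(min(100.0, max(0.0, v)))


def mediated_proportion(indirect_beta, total_beta, indirect_se, total_se=None,
                        method: str = "ratio"):
    """Mediated proportion in percent, with a 95% CI, both clipped to [0, 100].

    The proportion is the magnitude 100*|indirect/total|.  With the default
    ``ratio`` method the CI propagates the indirect effect's normal CI
    through the ratio at fixed total: bounds are 100*|bound/total| (lower
    bound 0 when the indirect CI spans zero).  ``bivariate`` instead applies
    the delta method to the ratio using both standard errors (requires
    ``total_se``).
    """
    if total_beta == 0:
        raise MRKitError("mediated proportion undefined for total effect = 0")
    prop_raw = 100.0 * abs(indirect_beta / total_beta)
    prop = _clip_pct(prop_raw)

    if method == "bivariate":
        if total_se is None or total_se <= 0:
            raise MRKitError("bivariate proportion CI requires a positive total_se")
        ratio = indirect_beta / total_beta
        var = (indirect_se / total_beta) ** 2 + (
            indirect_beta * total_se / total_beta**2
        ) ** 2
        half = Z95 * 100.0 * np.sqrt(var)
        lo, hi = _clip_pct(100 * abs(ratio) - half), _clip_pct(100 * abs(ratio) + half)
        return prop, (lo, hi)
    if method != "ratio":
        raise MRKitError(f"unknown proportion CI method {method!r}")

    ci_low = indirect_beta - Z95 * indirect_se
    ci_high = indirect_beta + Z95 * indirect_se
    if ci_low * ci_high < 0:  # indirect CI spans zero
        lo = 0.0
        hi = _clip_pct(100.0 * max(abs(ci_low), abs(ci_high)) / abs(total_beta))
    else:
        b1 = 100.0 * abs(ci_low / total_beta)
        b2 = 100.0 * abs(ci_high / total_beta)
        lo, hi = _clip_pct(min(b1, b2)), _clip_pct(max(b1, b2))
    return prop, (lo, hi)


def two_step_mediation(step1: MREstimate, step2: MREstimate, total: MREstimate) -> MediationResult:
    """Assemble a mediation result from step-1 (exposure->mediator), step-2
    (mediator->outcome) and total (exposure->outcome) MR estimates."""
    for name, est in (("step1", step1), ("step2", step2), ("total", total)):
        if est.scale != "beta":
            raise ScaleError(
                f"{name} estimate is on the {est.scale!r} scale; "
                "mediation requires additive (log-odds) betas"
            )
    ind = indirect_effect(step1.beta, step1.se, step2.beta, step2.se)
    prop, (plo, phi) = mediated_proportion(ind.beta, total.beta, ind.se, total.se)
    inconsistent = ind.beta * total.beta < 0
    if inconsistent:
        warnings.warn(
            "indirect and total effects have opposite signs (inconsistent "
            "mediation); the mediated proportion is a magnitude",
            stacklevel=2,
        )
    return MediationResult(
        total_beta=total.beta,
        total_se=total.se,
        a_beta=step1.beta,
        a_se=step1.se,
        b_beta=step2.beta,
        b_se=step2.se,
        indirect_beta=ind.beta,
        indirect_se=ind.se,
        indirect_ci_low=ind.ci_low,
        indirect_ci_high=ind.ci_high,
        indirect_pval=ind.pval,
        proportion=prop,
        proportion_ci_low=plo,
        proportion_ci_high=phi,
        inconsistent=inconsistent,
        provenance={
            "step1_method": step1.method,
            "step2_method": step2.method,
            "total_method": total.method,
            "step1_n_snps": step1.n_snps,
            "step2_n_snps": step2.n_snps,
            "total_n_snps": total.n_snps,
        },
    )
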