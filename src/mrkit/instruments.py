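"""Instrument selection: genome-wide significance, LD clumping, strength.

Selection follows the usual two-sample MR recipe: keep SNPs below the
genome-wide significance threshold (strictly, p < 5e-8 by default), greedily
clump them against an r^2 threshold so the retained panel is approximately
independent, and flag weak instruments by the per-SNP F statistic
F = (beta/se)^2 with the conventional F < 10 rule.  Weak instruments are
flagged, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInstrumentError
from .summary_io import LDMatrix, SummaryStatRecord

GENOME_WIDE_P = 5e-8
DEFAULT_CLUMP_R2 = 0.001
WEAK_F_THRESHOLD = 10.0


@dataclass
class InstrumentSelection:
    """Outcome of instrument selection for one exposure."""

    selected_ids: list
    records: list
    p_threshold: float
    r2_threshold: float | None
    f_stats: np.ndarray = field(default_factory=lambda: np.empty(0))
    weak_f_threshold: float = WEAK_F_THRESHOLD

    @property
    def mean_f(self) -> float:
        return float(np.mean(self.f_stats)) if self.f_stats.size else float("nan")

    @property
    def n_weak_flagged(self) -> int:
        return int(np.sum(self.f_stats < self.weak_f_threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.selected_ids,
                "P": [r.pval for r in self.records],
                "F": self.f_stats,
                "weak": self.f_stats < self.weak_f_threshold,
            }
        )


def select_by_pvalue(records, p_threshold=GENOME_WIDE_P):
    """Records with pval strictly below the threshold, order preserved."""
    if not (0 < p_threshold < 1):
        raise ConfigurationError(f"p_threshold must be in (0, 1), got {p_threshold}")
    return [r for r in records if r.pval < p_threshold]


def clump(records, ld: LDMatrix, r2_threshold=DEFAULT_CLUMP_R2):
    """Greedy LD clumping: scan by ascending p-value (ties by snp_id) and
    accept a SNP iff its r^2 with every already-accepted SNP is strictly
    below the threshold."""
    if not (0 < r2_threshold < 1):
        raise ConfigurationError(f"r2_threshold must be in (0, 1), got {r2_threshold}")
    for r in records:
        if r.snp_id not in ld:
            raise ConfigurationError(f"SNP {r.snp_id} missing from LD matrix")
    accepted = []
    for rec in sorted(records, key=lambda r: (r.pval, r.snp_id)):
        if all(ld.lookup(rec.snp_id, a.snp_id) < r2_threshold for a in accepted):
            accepted.append(rec)
    return accepted


def f_statistic(beta, se):
    """Per-SNP instrument-strength F statistic, the squared z-score (beta/se)^2."""
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DegenerateInstrumentError("se must be > 0 for the F statistic")
    f = (np.asarray(beta, dtype=float) / se) ** 2
    return float(f) if f.ndim == 0 else f


def select_instruments(
    records,
    ld: LDMatrix | None = None,
    p_threshold=GENOME_WIDE_P,
    r2_threshold=DEFAULT_CLUMP_R2,
    weak_f_threshold=WEAK_F_THRESHOLD,
    drop_weak=False,
) -> InstrumentSelection:
    """Significance filter, then clumping (when an LD panel is given), then
    per-SNP F statistics.  ``drop_weak`` removes F < threshold SNPs; the
    default keeps them and only flags."""
    sel = select_by_pvalue(records, p_threshold)
    if ld is not None:
        sel = clump(sel, ld, r2_threshold)
    f = np.array([f_statistic(r.beta, r.se) for r in sel])
    if drop_weak and sel:
        keep = f >= weak_f_threshold
        sel = [r for r, k in zip(sel, keep) if k]
        f = f[keep]
    return InstrumentSelection(
        selected_ids=[r.snp_id for r in sel],
        records=sel,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold if ld is not None else None,
        f_stats=f,
        weak_f_threshold=weak_f_threshold,
    )
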