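"""Study orchestration: univariable screen, sensitivity, MVMR, mediation.

``run_study`` executes the full design over delimited summary-statistics
files: per exposure-trait pair it selects instruments (significance +
clumping), harmonizes, runs IVW / weighted median / MR-Egger, and MR-PRESSO
where enough instruments survive; mediators whose step-1 IVW passes the
configured screen are carried into two-step mediation against each outcome,
with a Bonferroni threshold reported alongside nominal significance.
Failures are isolated per pair: one unreadable mediator file never aborts
the rest of the study.

Every stochastic step derives its seed deterministically from the run seed
and the pair label, so a rerun with the same configuration reproduces the
report bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, MRKitError
from .estimators import ivw, mr_egger, weighted_median
from .instruments import select_instruments
from .mediation import two_step_mediation
from .mvmr import harmonize_mv, mvmr_ivw
from .presso import presso
from .summary_io import harmonize, read_ld_matrix, read_summary_stats


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not (0 < alpha < 1):
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ConfigurationError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


@dataclass
class RunConfig:
    exposure_path: str
    outcome_paths: dict  # label -> path
    mediator_paths: dict = field(default_factory=dict)
    co_exposure_paths: dict = field(default_factory=dict)
    ld_path: str | None = None
    p_instrument: float = 5e-8
    r2_threshold: float = 0.001
    weak_f: float = 10.0
    ivw_mode: str = "auto"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    run_presso: bool = True
    alpha: float = 0.05
    n_tests: int = 36
    mediation_gate: str = "nominal"  # or "bonferroni"
    seed: int | None = None
    exposure_label: str = "exposure"

    def __post_init__(self):
        if not (0 < self.p_instrument < 1) or not (0 < self.r2_threshold < 1):
            raise ConfigurationError("instrument thresholds out of range")
        if self.mediation_gate not in ("nominal", "bonferroni"):
            raise ConfigurationError(f"unknown mediation gate {self.mediation_gate!r}")
        if self.seed is None:
            raise ConfigurationError("a seed is required (stochastic steps are enabled)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class StudyReport:
    univariable: pd.DataFrame
    presso: pd.DataFrame
    mvmr: pd.DataFrame | None
    mediation: pd.DataFrame
    failures: list
    provenance: dict

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.univariable.to_csv(outdir / "univariable.tsv", sep="\t", index=False)
        self.presso.to_csv(outdir / "presso.tsv", sep="\t", index=False)
        if self.mvmr is not None:
            self.mvmr.to_csv(outdir / "mvmr.tsv", sep="\t", index=False)
        self.mediation.to_csv(outdir / "mediation.tsv", sep="\t", index=False)
        with open(outdir / "run_log.yaml", "w") as fh:
            yaml.safe_dump({"provenance": self.provenance, "failures": self.failures}, fh)


def _pair_seed(base: int, label: str) -> int:
    return (int(base) * 1_000_003 + zlib.crc32(label.encode())) % (2**31)


def _estimate_rows(pair, h, cfg: RunConfig, bonf: float):
    rows = []
    ests = [ivw(h, mode=cfg.ivw_mode)]
    if h.n_snps >= 3:
        ests.append(weighted_median(h, n_boot=cfg.n_boot, seed=_pair_seed(cfg.seed, pair)))
        eg = mr_egger(h)
        ests.append(eg.slope)
    for e in ests:
        rows.append(
            {
                "pair": pair,
                "method": e.method,
                "beta": e.beta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pval": e.pval,
                "n_snps": e.n_snps,
                "or_value": e.or_value,
                "or_ci_low": e.or_ci_low,
                "or_ci_high": e.or_ci_high,
                "sig_nominal": e.pval < cfg.alpha,
                "sig_bonferroni": e.pval < bonf,
            }
        )
    if h.n_snps >= 3:
        rows.append(
            {
                "pair": pair,
                "method": "egger_intercept",
                "beta": eg.intercept,
                "se": eg.intercept_se,
                "ci_low": eg.intercept - 1.96 * eg.intercept_se,
                "ci_high": eg.intercept + 1.96 * eg.intercept_se,
                "pval": eg.intercept_pval,
                "n_snps": h.n_snps,
                "or_value": np.nan,
                "or_ci_low": np.nan,
                "or_ci_high": np.nan,
                "sig_nominal": eg.intercept_pval < cfg.alpha,
                "sig_bonferroni": eg.intercept_pval < bonf,
            }
        )
    return rows


def run_study(config: RunConfig) -> StudyReport:
    """Execute the full study flow; see the module docstring."""
    cfg = config
    bonf = bonferroni_threshold(cfg.alpha, cfg.n_tests)
    ld = read_ld_matrix(cfg.ld_path) if cfg.ld_path else None

    failures: list = []
    uni_rows: list = []
    presso_rows: list = []
    med_rows: list = []
    ivw_by_pair: dict = {}
    harmonized: dict = {}

    def guard(stage, pair, fn):
        try:
            return fn()
        except (MRKitError, OSError, ValueError) as exc:
            failures.append({"stage": stage, "pair": pair, "error": str(exc)})
            return None

    def load(path, label):
        return guard("read", label, lambda: read_summary_stats(path))

    exposure = load(cfg.exposure_path, cfg.exposure_label)
    if exposure is None:
        raise ConfigurationError(f"cannot read exposure file {cfg.exposure_path}")
    traits = {cfg.exposure_label: exposure}
    for label, path in {**cfg.mediator_paths, **cfg.outcome_paths}.items():
        rec = load(path, label)
        if rec is not None:
            traits[label] = rec

    selections = {}

    def instruments_for(label):
        if label not in selections and label in traits:
            selections[label] = guard(
                "instrument_selection",
                label,
                lambda: select_instruments(
                    traits[label], ld, cfg.p_instrument, cfg.r2_threshold, cfg.weak_f
                ),
            )
        return selections.get(label)

    def univariable(exp_label, out_label):
        pair = f"{exp_label}->{out_label}"
        sel = instruments_for(exp_label)
        if sel is None or out_label not in traits:
            return
        if not sel.records:
            failures.append({"stage": "instrument_selection", "pair": pair,
                             "error": "no genome-wide-significant instruments"})
            return
        h = guard("harmonize", pair, lambda: harmonize(sel.records, traits[out_label]))
        if h is None:
            return
        harmonized[pair] = h
        rows = guard("estimate", pair, lambda: _estimate_rows(pair, h, cfg, bonf))
        if rows is None:
            return
        uni_rows.extend(rows)
        ivw_by_pair[pair] = next(r for r in rows if r["method"].startswith("ivw"))
        if cfg.run_presso and h.n_snps >= 4:
            pr = guard(
                "presso",
                pair,
                lambda: presso(h, n_sim=cfg.presso_n_sim, seed=_pair_seed(cfg.seed, pair)),
            )
            if pr is not None:
                presso_rows.append(
                    {
                        "pair": pair,
                        "global_rss": pr.global_rss,
                        "global_pval": pr.global_pval,
                        "n_outliers": len(pr.outlier_ids),
                        "outlier_ids": ",".join(pr.outlier_ids),
                        "distortion_pval": pr.distortion_pval,
                        "corrected_beta": pr.corrected.beta,
                        "corrected_se": pr.corrected.se,
                        "corrected_pval": pr.corrected.pval,
                    }
                )

    for out_label in cfg.outcome_paths:
        univariable(cfg.exposure_label, out_label)
    for med_label in cfg.mediator_paths:
        univariable(cfg.exposure_label, med_label)

    gate = cfg.alpha if cfg.mediation_gate == "nominal" else bonf
    gated = [
        m
        for m in cfg.mediator_paths
        if (row := ivw_by_pair.get(f"{cfg.exposure_label}->{m}")) is not None
        and row["pval"] < gate
    ]

    for med_label in gated:
        for out_label in cfg.outcome_paths:
            univariable(med_label, out_label)
            pair = f"{med_label}->{out_label}"
            step1 = ivw_by_pair.get(f"{cfg.exposure_label}->{med_label}")
            step2 = ivw_by_pair.get(pair)
            total = ivw_by_pair.get(f"{cfg.exposure_label}->{out_label}")
            if step1 is None or step2 is None or total is None:
                continue

            def _mediate():
                h1 = harmonized[f"{cfg.exposure_label}->{med_label}"]
                h2 = harmonized[pair]
                ht = harmonized[f"{cfg.exposure_label}->{out_label}"]
                return two_step_mediation(
                    ivw(h1, mode=cfg.ivw_mode), ivw(h2, mode=cfg.ivw_mode),
                    ivw(ht, mode=cfg.ivw_mode)
                )

            res = guard("mediation", f"{med_label}x{out_label}", _mediate)
            if res is None:
                continue
            med_rows.append(
                {
                    "mediator": med_label,
                    "outcome": out_label,
                    "total_beta": res.total_beta,
                    "a_beta": res.a_beta,
                    "b_beta": res.b_beta,
                    "indirect_beta": res.indirect_beta,
                    "indirect_se": res.indirect_se,
                    "indirect_ci_low": res.indirect_ci_low,
                    "indirect_ci_high": res.indirect_ci_high,
                    "indirect_pval": res.indirect_pval,
                    "proportion": res.proportion,
                    "proportion_ci_low": res.proportion_ci_low,
                    "proportion_ci_high": res.proportion_ci_high,
                    "inconsistent": res.inconsistent,
                }
            )

    mv_df = None
    if cfg.co_exposure_paths:
        def _mv():
            rows = []
            co = {}
            for label, path in cfg.co_exposure_paths.items():
                co[label] = read_summary_stats(path)
            labels = [cfg.exposure_label] + list(co)
            pool = set()
            for lab in labels:
                sel = instruments_for(lab) if lab in traits else None
                if sel is None and lab in co:
                    sel = select_instruments(co[lab], ld, cfg.p_instrument, cfg.r2_threshold)
                if sel is not None:
                    pool |= set(sel.selected_ids)
            lists = [traits[cfg.exposure_label]] + list(co.values())
            for out_label in cfg.outcome_paths:
                if out_label not in traits:
                    continue
                m = harmonize_mv(lists, traits[out_label], labels=labels,
                                 snp_ids=pool or None)
                res = mvmr_ivw(m)
                df = res.to_frame()
                df.insert(0, "outcome", out_label)
                rows.append(df)
            return pd.concat(rows, ignore_index=True) if rows else None

        mv_df = guard("mvmr", "multivariable", _mv)

    uni_cols = ["pair", "method", "beta", "se", "ci_low", "ci_high", "pval", "n_snps",
                "or_value", "or_ci_low", "or_ci_high", "sig_nominal", "sig_bonferroni"]
    presso_cols = ["pair", "global_rss", "global_pval", "n_outliers", "outlier_ids",
                   "distortion_pval", "corrected_beta", "corrected_se", "corrected_pval"]
    med_cols = ["mediator", "outcome", "total_beta", "a_beta", "b_beta", "indirect_beta",
                "indirect_se", "indirect_ci_low", "indirect_ci_high", "indirect_pval",
                "proportion", "proportion_ci_low", "proportion_ci_high", "inconsistent"]
    provenance = {
        "mrkit_version": __version__,
        "config": cfg.to_dict(),
        "bonferroni_threshold": bonf,
        "gated_mediators": gated,
    }
    return StudyReport(
        univariable=pd.DataFrame(uni_rows, columns=uni_cols),
        presso=pd.DataFrame(presso_rows, columns=presso_cols),
        mvmr=mv_df,
        mediation=pd.DataFrame(med_rows, columns=med_cols),
        failures=failures,
        provenance=provenance,
    )
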