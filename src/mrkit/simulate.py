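"""Synthetic two-sample GWAS summary statistics under a known causal model.

Summary statistics are simulated directly at the summary level (no
genotypes): per instrument j a true SNP->exposure effect gamma_j is drawn
from a Gaussian, the observed exposure effect adds Gaussian noise with the
study's standard error, and the observed outcome effect is built from the
structural model

    beta_outcome_j = theta * gamma_j + alpha_j  (+ b * a * gamma_j with a mediator chain)

plus Gaussian noise, where alpha_j is a per-SNP horizontal-pleiotropy
offset.  Exposure and outcome noise are independent — a strict two-sample
design with no sample overlap.  Null SNPs (gamma = 0) can be appended to
exercise instrument selection, a configurable fraction of SNPs gets
palindromic alleles, and outcome records can be emitted on the swapped
allele to exercise harmonization.  Every draw flows from the mandatory
seed, and the generating truth is returned as a serializable record.

Defaults describe a well-powered desk-scale study: 30 instruments with
per-SNP effects around 0.25 (sd 0.08) measured with se 0.02, i.e. mean
instrument F around 150 ("strong instruments"), outcome se 0.05, no causal
effect and no pleiotropy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .summary_io import LDMatrix, SummaryStatRecord, write_ld_matrix, write_summary_stats

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class MediatorChain:
    """Exposure -> mediator -> outcome chain: total effect = a*b + c_prime."""

    a: float
    b: float
    c_prime: float


@dataclass(frozen=True)
class Pleiotropy:
    """Per-SNP outcome offsets alpha_j.

    ``none``: all zero.  ``balanced``: alpha ~ N(0, magnitude).
    ``directional``: alpha ~ N(magnitude, sd) (sd 0 gives a constant
    offset).  ``inside_violating``: alpha = magnitude * gamma + N(0, sd),
    correlated with instrument strength.  ``frac`` limits the offsets to a
    random subset of instruments.
    """

    mode: str = "none"
    magnitude: float = 0.0
    sd: float = 0.0
    frac: float = 1.0


@dataclass(frozen=True)
class LDBlocks:
    sizes: tuple
    r2: float = 0.8


@dataclass
class SimConfig:
    seed: int
    J: int = 30
    K: int = 1
    gamma_mean: float = 0.25
    gamma_sd: float = 0.08
    se_exposure: float | None = 0.02
    se_outcome: float | None = 0.05
    se_mediator: float | None = None
    theta: float | tuple = 0.0
    mediator_chain: MediatorChain | None = None
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    n_null_snps: int = 0
    ld_blocks: LDBlocks | None = None
    n_exposure: int = 400_000
    n_outcome: int = 30_000
    n_mediator: int = 300_000
    fraction_palindromic: float = 0.0
    allele_flip_fraction: float = 0.0

    def __post_init__(self):
        if self.J < 1:
            raise ConfigurationError("J must be >= 1")
        if self.gamma_sd <= 0:
            raise ConfigurationError("gamma_sd must be > 0")
        if self.pleiotropy.magnitude < 0:
            raise ConfigurationError("pleiotropy magnitude must be >= 0")
        if self.pleiotropy.mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ConfigurationError(f"unknown pleiotropy mode {self.pleiotropy.mode!r}")
        if self.mediator_chain is not None and self.K != 1:
            raise ConfigurationError("a mediator chain requires K = 1")
        # SEs derived from nominal sample sizes when not given explicitly
        if self.se_exposure is None:
            self.se_exposure = 1.0 / np.sqrt(self.n_exposure)
        if self.se_outcome is None:
            self.se_outcome = 1.0 / np.sqrt(self.n_outcome)
        if self.se_mediator is None:
            self.se_mediator = self.se_outcome
        thetas = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if thetas.size == 1 and self.K > 1:
            thetas = np.repeat(thetas, self.K)
        if thetas.size != self.K:
            raise ConfigurationError(f"theta must have length K={self.K}")
        self.theta = tuple(float(t) for t in thetas)


@dataclass
class SimTruth:
    """Ground truth of one synthetic dataset; round-trips through JSON."""

    seed: int
    thetas: tuple
    a: float | None
    b: float | None
    c_prime: float | None
    total: tuple
    gammas: list  # (J + n_null) x K nested lists
    alphas: list

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        d["thetas"] = tuple(d["thetas"])
        d["total"] = tuple(d["total"])
        return cls(**d)


@dataclass
class SimData:
    exposures: list  # K lists of SummaryStatRecord
    mediator: list | None
    outcome: list
    ld: LDMatrix
    truth: SimTruth

    @property
    def exposure(self):
        return self.exposures[0]


def make_ld_matrix(block_sizes, within_r2, snp_ids=None) -> LDMatrix:
    """Block-diagonal r^2 matrix: ``within_r2`` inside blocks, 0 between."""
    sizes = [int(s) for s in block_sizes]
    if any(s < 1 for s in sizes):
        raise ConfigurationError("block sizes must be >= 1")
    if not (0 <= within_r2 < 1):
        raise ConfigurationError("within-block r^2 must be in [0, 1)")
    total = sum(sizes)
    r2 = np.zeros((total, total))
    start = 0
    for s in sizes:
        r2[start : start + s, start : start + s] = within_r2
        start += s
    np.fill_diagonal(r2, 1.0)
    if snp_ids is None:
        snp_ids = [f"rs{i + 1:06d}" for i in range(total)]
    elif len(snp_ids) != total:
        raise ConfigurationError("snp_ids length must equal the sum of block sizes")
    return LDMatrix(snp_ids=list(snp_ids), r2=r2)


def _pvals(beta, se):
    return np.maximum(2 * stats.norm.sf(np.abs(beta / se)), 5e-324)


def _records(ids, ea, oa, eaf, beta, se, n):
    p = _pvals(beta, se)
    return [
        SummaryStatRecord(ids[j], ea[j], oa[j], float(beta[j]), float(se),
                          float(p[j]), int(n), eaf=float(eaf[j]))
        for j in range(len(ids))
    ]


def _draw_alphas(cfg: SimConfig, rng, gammas):
    total = len(gammas)
    alphas = np.zeros(total)
    p = cfg.pleiotropy
    if p.mode == "none" or p.magnitude == 0 and p.sd == 0:
        return alphas
    affected = np.zeros(total, dtype=bool)
    n_aff = int(round(p.frac * cfg.J))
    affected[rng.choice(cfg.J, size=n_aff, replace=False)] = True  # instruments only
    if p.mode == "balanced":
        alphas[affected] = rng.normal(0.0, p.magnitude, size=n_aff)
    elif p.mode == "directional":
        alphas[affected] = rng.normal(p.magnitude, p.sd, size=n_aff) if p.sd > 0 else p.magnitude
    elif p.mode == "inside_violating":
        alphas[affected] = p.magnitude * gammas[affected] + (
            rng.normal(0.0, p.sd, size=n_aff) if p.sd > 0 else 0.0
        )
    return alphas


def simulate(config: SimConfig) -> SimData:
    """Draw one two-sample summary-statistics dataset under the config's DAG."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    total = cfg.J + cfg.n_null_snps
    ids = [f"rs{j + 1:06d}" for j in range(total)]

    gammas = np.zeros((total, cfg.K))
    gammas[: cfg.J] = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=(cfg.J, cfg.K))

    # alleles and frequencies, shared across studies
    is_pal = rng.random(total) < cfg.fraction_palindromic
    pair_idx = rng.integers(0, 4 if cfg.fraction_palindromic > 0 else 8, size=total)
    pairs = [
        _PALINDROMIC[pair_idx[j] % 4] if is_pal[j] else _NONPALINDROMIC[pair_idx[j] % 8]
        for j in range(total)
    ]
    ea = [p[0] for p in pairs]
    oa = [p[1] for p in pairs]
    eaf = rng.uniform(0.05, 0.95, size=total)

    exposures = []
    for k in range(cfg.K):
        beta_obs = gammas[:, k] + rng.normal(0.0, cfg.se_exposure, size=total)
        exposures.append(_records(ids, ea, oa, eaf, beta_obs, cfg.se_exposure, cfg.n_exposure))

    alphas = _draw_alphas(cfg, rng, gammas[:, 0])

    mediator = None
    if cfg.mediator_chain is not None:
        ch = cfg.mediator_chain
        med_true = ch.a * gammas[:, 0]
        med_obs = med_true + rng.normal(0.0, cfg.se_mediator, size=total)
        mediator = _records(ids, ea, oa, eaf, med_obs, cfg.se_mediator, cfg.n_mediator)
        out_true = ch.c_prime * gammas[:, 0] + ch.b * med_true + alphas
        totals = (ch.a * ch.b + ch.c_prime,)
    else:
        out_true = gammas @ np.asarray(cfg.theta) + alphas
        totals = cfg.theta

    out_obs = out_true + rng.normal(0.0, cfg.se_outcome, size=total)
    flip = rng.random(total) < cfg.allele_flip_fraction
    out_ea = [oa[j] if flip[j] else ea[j] for j in range(total)]
    out_oa = [ea[j] if flip[j] else oa[j] for j in range(total)]
    out_eaf = np.where(flip, 1.0 - eaf, eaf)
    out_beta = np.where(flip, -out_obs, out_obs)
    outcome = _records(ids, out_ea, out_oa, out_eaf, out_beta, cfg.se_outcome, cfg.n_outcome)

    if cfg.ld_blocks is not None:
        sizes = list(cfg.ld_blocks.sizes)
        covered = sum(sizes)
        if covered > total:
            raise ConfigurationError("ld_blocks cover more SNPs than simulated")
        sizes += [1] * (total - covered)
        ld = make_ld_matrix(sizes, cfg.ld_blocks.r2, snp_ids=ids)
    else:
        ld = make_ld_matrix([1] * total, 0.0, snp_ids=ids)

    ch = cfg.mediator_chain
    truth = SimTruth(
        seed=cfg.seed,
        thetas=tuple(cfg.theta),
        a=ch.a if ch else None,
        b=ch.b if ch else None,
        c_prime=ch.c_prime if ch else None,
        total=tuple(float(t) for t in np.atleast_1d(totals)),
        gammas=gammas.tolist(),
        alphas=alphas.tolist(),
    )
    return SimData(exposures=exposures, mediator=mediator, outcome=outcome, ld=ld, truth=truth)


def write_bundle(sim: SimData, outdir):
    """Write a simulated dataset in the summary-stats dialect plus LD and truth."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(sim.exposures) == 1:
        write_summary_stats(sim.exposure, outdir / "exposure.tsv")
    else:
        for k, rec in enumerate(sim.exposures):
            write_summary_stats(rec, outdir / f"exposure_{k + 1}.tsv")
    if sim.mediator is not None:
        write_summary_stats(sim.mediator, outdir / "mediator.tsv")
    write_summary_stats(sim.outcome, outdir / "outcome.tsv")
    write_ld_matrix(sim.ld, outdir / "ld.tsv")
    (outdir / "truth.json").write_text(sim.truth.to_json())


# ---------------------------------------------------------------------------
# Multi-trait study bundles (one exposure, several mediators, several outcomes)
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """A full mediation-study bundle.

    ``a`` gives the exposure->mediator effect per mediator; ``b[m][o]`` the
    mediator->outcome effects; ``c_prime[o]`` the direct exposure->outcome
    effects.  Each mediator also receives ``j_mediator`` instruments of its
    own (independent of the exposure), so step-2 MR has a proper instrument
    set.  The implied total effect on outcome o is
    c_prime[o] + sum_m a[m] * b[m][o].
    """

    seed: int
    a: tuple
    b: tuple  # tuple of per-mediator tuples, one entry per outcome
    c_prime: tuple
    j_exposure: int = 25
    j_mediator: int = 25
    n_null_snps: int = 50
    gamma_mean: float = 0.25
    gamma_sd: float = 0.08
    se_exposure: float = 0.02
    se_mediator: float = 0.03
    se_outcome: float = 0.05
    mediator_labels: tuple | None = None
    outcome_labels: tuple | None = None


@dataclass
class StudyData:
    traits: dict  # label -> list[SummaryStatRecord]
    exposure_label: str
    mediator_labels: list
    outcome_labels: list
    ld: LDMatrix
    truth: dict


def simulate_study(cfg: StudyConfig) -> StudyData:
    """Simulate an exposure, M mediators and O outcomes over one SNP panel."""
    M = len(cfg.a)
    O = len(cfg.c_prime)
    if any(len(bm) != O for bm in cfg.b) or len(cfg.b) != M:
        raise ConfigurationError("b must be an M x O nested tuple")
    med_labels = list(cfg.mediator_labels or [f"mediator_{m + 1}" for m in range(M)])
    out_labels = list(cfg.outcome_labels or [f"outcome_{o + 1}" for o in range(O)])

    rng = np.random.default_rng(cfg.seed)
    total = cfg.j_exposure + M * cfg.j_mediator + cfg.n_null_snps
    ids = [f"rs{j + 1:06d}" for j in range(total)]
    ea = ["A"] * total
    oa = ["G"] * total
    eaf = rng.uniform(0.05, 0.95, size=total)

    # true per-SNP effects on the exposure and on each mediator
    gamma = np.zeros(total)
    gamma[: cfg.j_exposure] = rng.normal(cfg.gamma_mean, cfg.gamma_sd, cfg.j_exposure)
    med_true = np.zeros((total, M))
    for m in range(M):
        lo = cfg.j_exposure + m * cfg.j_mediator
        own = np.zeros(total)
        own[lo : lo + cfg.j_mediator] = rng.normal(cfg.gamma_mean, cfg.gamma_sd, cfg.j_mediator)
        med_true[:, m] = cfg.a[m] * gamma + own

    traits = {}
    exp_obs = gamma + rng.normal(0.0, cfg.se_exposure, total)
    traits["exposure"] = _records(ids, ea, oa, eaf, exp_obs, cfg.se_exposure, 400_000)
    for m, lab in enumerate(med_labels):
        obs = med_true[:, m] + rng.normal(0.0, cfg.se_mediator, total)
        traits[lab] = _records(ids, ea, oa, eaf, obs, cfg.se_mediator, 300_000)
    b = np.asarray(cfg.b, dtype=float)
    for o, lab in enumerate(out_labels):
        out_true = cfg.c_prime[o] * gamma + med_true @ b[:, o]
        obs = out_true + rng.normal(0.0, cfg.se_outcome, total)
        traits[lab] = _records(ids, ea, oa, eaf, obs, cfg.se_outcome, 30_000)

    ld = make_ld_matrix([1] * total, 0.0, snp_ids=ids)
    truth = {
        "seed": cfg.seed,
        "a": list(cfg.a),
        "b": [list(bm) for bm in cfg.b],
        "c_prime": list(cfg.c_prime),
        "total": [
            float(cfg.c_prime[o] + sum(cfg.a[m] * cfg.b[m][o] for m in range(M)))
            for o in range(O)
        ],
    }
    return StudyData(
        traits=traits,
        exposure_label="exposure",
        mediator_labels=med_labels,
        outcome_labels=out_labels,
        ld=ld,
        truth=truth,
    )


def write_study_bundle(study: StudyData, outdir) -> dict:
    """Write every trait file plus the LD matrix; returns label -> path."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label, records in study.traits.items():
        p = outdir / f"{label}.tsv"
        write_summary_stats(records, p)
        paths[label] = str(p)
    write_ld_matrix(study.ld, outdir / "ld.tsv")
    paths["__ld__"] = str(outdir / "ld.tsv")
    (outdir / "truth.json").write_text(json.dumps(study.truth, indent=1))
    return paths
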