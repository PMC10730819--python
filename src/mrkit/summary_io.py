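"""Reading, writing and harmonizing GWAS summary statistics.

The on-disk dialect is a tab-separated table with a header row and canonical
columns ``SNP EA OA EAF BETA SE P N`` (EAF optional).  Aliased headers are
supported through an explicit column mapping.  Harmonization aligns an
exposure and an outcome study onto the exposure's effect-allele convention:
matching allele pairs are kept, swapped pairs have the outcome effect negated
(and EAF complemented), palindromic (A/T, C/G) and allele-incompatible SNPs
are dropped and counted.

Matching is by SNP identifier only; duplicated identifiers are rejected
rather than disambiguated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, HarmonizationError, ParseError

VALID_ALLELES = frozenset("ACGT")
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: canonical column order for the TSV dialect
CANONICAL_COLUMNS = ("SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N")
REQUIRED_COLUMNS = ("SNP", "EA", "OA", "BETA", "SE", "P", "N")


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait scale
    (log-odds for binary traits); ``eaf`` is the effect-allele frequency and
    may be missing (None) — harmonization uses alleles only.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: float | None = None

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: alleles must be one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0 (got {self.se})")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.snp_id}: pval must be in (0, 1] (got {self.pval})")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.snp_id}: eaf must be in [0, 1] (got {self.eaf})")
        if self.n < 1:
            raise ValueError(f"{self.snp_id}: n must be >= 1 (got {self.n})")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    @property
    def is_palindromic(self) -> bool:
        return self.alleles in PALINDROMIC_PAIRS

    def flipped(self) -> "SummaryStatRecord":
        """Return the same association expressed for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass
class HarmonizedSet:
    """Per-SNP aligned exposure and outcome effects, ready for MR."""

    snp_ids: list
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    effect_alleles: list = field(default_factory=list)
    other_alleles: list = field(default_factory=list)
    n_dropped_palindromic: int = 0
    n_dropped_incompatible: int = 0
    n_not_shared: int = 0

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, indices) -> "HarmonizedSet":
        """A new set restricted to the given positional indices (order kept)."""
        idx = list(indices)
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in idx],
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            beta_outcome=self.beta_outcome[idx],
            se_outcome=self.se_outcome[idx],
            effect_alleles=[self.effect_alleles[i] for i in idx] if self.effect_alleles else [],
            other_alleles=[self.other_alleles[i] for i in idx] if self.other_alleles else [],
        )

    def as_record_pairs(self):
        """Rebuild (exposure, outcome) record lists from the aligned arrays.

        P-values are recomputed from z = beta/se; sample sizes are not stored
        in the harmonized container and are set to 1.
        """
        from scipy import stats

        exp, out = [], []
        for j, sid in enumerate(self.snp_ids):
            ea = self.effect_alleles[j] if self.effect_alleles else "A"
            oa = self.other_alleles[j] if self.other_alleles else "G"
            for lst, b, s in (
                (exp, self.beta_exposure[j], self.se_exposure[j]),
                (out, self.beta_outcome[j], self.se_outcome[j]),
            ):
                p = float(2 * stats.norm.sf(abs(b / s))) if s > 0 else 1.0
                lst.append(
                    SummaryStatRecord(sid, ea, oa, float(b), float(s), max(p, 5e-324), 1)
                )
        return exp, out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.snp_ids,
                "EA": self.effect_alleles or [""] * self.n_snps,
                "OA": self.other_alleles or [""] * self.n_snps,
                "BETA_EXP": self.beta_exposure,
                "SE_EXP": self.se_exposure,
                "BETA_OUT": self.beta_outcome,
                "SE_OUT": self.se_outcome,
            }
        )


@dataclass
class LDMatrix:
    """Squared-correlation (r^2) matrix over an ordered SNP panel."""

    snp_ids: list
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ConfigurationError(f"LD matrix shape {self.r2.shape} does not match {k} SNP ids")
        if not np.array_equal(self.r2, self.r2.T):
            raise ConfigurationError("LD matrix is not symmetric")
        if not np.all(np.diag(self.r2) == 1.0):
            raise ConfigurationError("LD matrix diagonal must be exactly 1")
        if self.r2.min() < 0 or self.r2.max() > 1:
            raise ConfigurationError("LD r^2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self._index) != k:
            raise ConfigurationError("duplicate SNP ids in LD matrix")

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise ConfigurationError(f"SNP {exc.args[0]} missing from LD matrix") from None

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


def _parse_float(value, column, line_no):
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(f"line {line_no}: non-numeric {column} value {value!r}") from None


def read_summary_stats(path, column_map=None, sep="\t"):
    """Read a summary-statistics table into validated records.

    ``column_map`` maps file header names onto the canonical names, e.g.
    ``{"rsid": "SNP", "effect": "BETA"}``.  Rows violating record invariants
    (se <= 0, p outside (0,1], identical alleles, ...) are rejected and
    reported with their line numbers via a warning; structural problems
    (missing columns, non-numeric effect sizes) raise.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {missing}")

    has_eaf = "EAF" in df.columns
    records, rejected = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header
        d = dict(zip(df.columns, row))
        beta = _parse_float(d["BETA"], "BETA", line_no)
        se = _parse_float(d["SE"], "SE", line_no)
        pval = _parse_float(d["P"], "P", line_no)
        n = int(_parse_float(d["N"], "N", line_no))
        eaf = None
        if has_eaf and d.get("EAF") not in (None, "", "NA"):
            if not (isinstance(d["EAF"], float) and np.isnan(d["EAF"])):
                eaf = _parse_float(d["EAF"], "EAF", line_no)
        rec = SummaryStatRecord(
            snp_id=str(d["SNP"]),
            effect_allele=str(d["EA"]).upper(),
            other_allele=str(d["OA"]).upper(),
            beta=beta,
            se=se,
            pval=pval,
            n=n,
            eaf=eaf,
        )
        try:
            rec.validate()
        except ValueError as exc:
            rejected.append((line_no, str(exc)))
            continue
        records.append(rec)
    if rejected:
        details = "; ".join(f"line {ln}: {msg}" for ln, msg in rejected)
        warnings.warn(f"{path}: rejected {len(rejected)} row(s) — {details}", stacklevel=2)
    return records


def write_summary_stats(records, path, sep="\t"):
    """Write records in the canonical TSV dialect (missing EAF as empty)."""
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "EA": [r.effect_allele for r in records],
            "OA": [r.other_allele for r in records],
            "EAF": [r.eaf if r.eaf is not None else "" for r in records],
            "BETA": [repr(r.beta) for r in records],
            "SE": [repr(r.se) for r in records],
            "P": [repr(r.pval) for r in records],
            "N": [r.n for r in records],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def read_ld_matrix(path, sep="\t") -> LDMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return LDMatrix(snp_ids=list(df.index.astype(str)), r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path, sep="\t"):
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep=sep)


def _check_unique(records, label):
    ids = [r.snp_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise HarmonizationError(f"duplicate SNP ids in {label} records: {dupes}")


def harmonize(exposure, outcome) -> HarmonizedSet:
    """Align exposure and outcome records onto the exposure's effect allele.

    Palindromic SNPs are always dropped (no frequency-based rescue);
    allele-incompatible pairs are dropped; a swapped outcome record has its
    beta negated and EAF complemented.  Raises if no instruments survive.
    """
    if not exposure or not outcome:
        raise HarmonizationError("exposure and outcome record lists must be non-empty")
    _check_unique(exposure, "exposure")
    _check_unique(outcome, "outcome")
    out_by_id = {r.snp_id: r for r in outcome}

    ids, ea, oa = [], [], []
    bx, sx, by, sy = [], [], [], []
    n_pal = n_inc = n_miss = 0
    for e in exposure:
        o = out_by_id.get(e.snp_id)
        if o is None:
            n_miss += 1
            continue
        if e.is_palindromic or o.is_palindromic:
            n_pal += 1
            continue
        if o.alleles != e.alleles:
            n_inc += 1
            continue
        if o.effect_allele != e.effect_allele:
            o = o.flipped()
        ids.append(e.snp_id)
        ea.append(e.effect_allele)
        oa.append(e.other_allele)
        bx.append(e.beta)
        sx.append(e.se)
        by.append(o.beta)
        sy.append(o.se)

    if not ids:
        raise HarmonizationError(
            "no shared instruments after harmonization "
            f"(palindromic={n_pal}, incompatible={n_inc}, not shared={n_miss})"
        )
    return HarmonizedSet(
        snp_ids=ids,
        beta_exposure=np.array(bx),
        se_exposure=np.array(sx),
        beta_outcome=np.array(by),
        se_outcome=np.array(sy),
        effect_alleles=ea,
        other_alleles=oa,
        n_dropped_palindromic=n_pal,
        n_dropped_incompatible=n_inc,
        n_not_shared=n_miss,
    )
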