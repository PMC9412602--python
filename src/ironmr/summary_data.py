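"""Reading, validating, selecting and harmonising GWAS summary statistics.

Two-sample Mendelian randomisation starts from per-SNP association summary
statistics estimated in two non-overlapping samples: one for the exposure
(here, iron-status biomarkers) and one for the outcome (heart failure).
This module turns raw summary tables into analysis-ready instrument sets:

* :func:`read_summary_table` parses a TSV into :class:`GwasRecord` rows;
* :func:`select_instruments` applies the genome-wide significance filter;
* :func:`ld_prune` greedily removes variants in linkage disequilibrium;
* :func:`find_proxy` substitutes a correlated proxy when the outcome GWAS
  lacks a selected variant;
* :func:`harmonise` aligns exposure and outcome records to the same effect
  allele (dropping strand-ambiguous palindromic variants);
* :func:`f_statistic` / :func:`filter_weak` guard against weak instruments.

Every removal is recorded in a selection log so the filter cascade is
auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GwasRecord",
    "HarmonisedInstrument",
    "InstrumentSet",
    "LdMatrix",
    "read_summary_table",
    "select_instruments",
    "ld_prune",
    "find_proxy",
    "is_palindromic",
    "harmonise",
    "f_statistic",
    "filter_weak",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default column names of the summary-statistic TSV dialect
DEFAULT_DIALECT = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

_MANDATORY = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval")


class SummaryDataError(ValueError):
    """Raised for malformed summary-statistic inputs."""


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele change in the trait (SD units for
    quantitative traits); ``eaf`` is the effect-allele frequency.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    chrom: str = ""
    pos: int = 0
    n: int | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise SummaryDataError(f"{self.snp_id}: standard error must be > 0, got {self.se}")
        if not 0.0 <= self.eaf <= 1.0:
            raise SummaryDataError(f"{self.snp_id}: EAF must lie in [0, 1], got {self.eaf}")
        if not 0.0 < self.pval <= 1.0:
            raise SummaryDataError(f"{self.snp_id}: p-value must lie in (0, 1], got {self.pval}")
        if self.effect_allele == self.other_allele:
            raise SummaryDataError(f"{self.snp_id}: effect and other allele are identical")
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())


@dataclass(frozen=True)
class HarmonisedInstrument:
    """Per-SNP aligned exposure/outcome effect pair after allele harmonisation.

    After harmonisation both betas refer to the same effect allele, so the
    Wald ratio ``beta_y / beta_x`` is well defined.
    """

    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: float = math.nan
    eaf_y: float = math.nan
    f_stat: float = math.nan
    proxy_of: str = ""

    def __post_init__(self) -> None:
        if self.se_x <= 0 or self.se_y <= 0:
            raise SummaryDataError(f"{self.snp_id}: standard errors must be > 0")

    def flipped(self) -> "HarmonisedInstrument":
        """Recode to the opposite effect allele (negate both betas)."""
        return replace(
            self,
            beta_x=-self.beta_x,
            beta_y=-self.beta_y,
            eaf_x=1.0 - self.eaf_x,
            eaf_y=1.0 - self.eaf_y,
        )


@dataclass
class InstrumentSet:
    """Retained instruments for one exposure plus the audit trail of removals."""

    exposure_name: str
    instruments: list[HarmonisedInstrument]
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [i.snp_id for i in self.instruments]
        if len(ids) != len(set(ids)):
            raise SummaryDataError(f"{self.exposure_name}: duplicate snp_id in instrument set")

    def log(self, snp_id: str, rule: str, detail: str = "") -> None:
        self.selection_log.append((snp_id, rule, detail))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "snp_id": i.snp_id,
                    "beta_x": i.beta_x,
                    "se_x": i.se_x,
                    "beta_y": i.beta_y,
                    "se_y": i.se_y,
                    "eaf_x": i.eaf_x,
                    "eaf_y": i.eaf_y,
                    "f_stat": i.f_stat,
                    "proxy_of": i.proxy_of,
                }
                for i in self.instruments
            ]
        )

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.selection_log, columns=["snp_id", "rule", "detail"])


class LdMatrix:
    """Symmetric pairwise LD r-squared lookup keyed by rsID pairs.

    Missing pairs are treated as r² = 0 (unlinked) and recorded in
    :attr:`missing_pairs` so the assumption is auditable.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float]):
        self._r2: dict[tuple[str, str], float] = {}
        self.missing_pairs: list[tuple[str, str]] = []
        for (a, b), r2 in entries.items():
            if not 0.0 <= r2 <= 1.0:
                raise SummaryDataError(f"LD r2 out of [0,1] for ({a},{b}): {r2}")
            key = (min(a, b), max(a, b))
            if key in self._r2 and not math.isclose(self._r2[key], r2, abs_tol=1e-12):
                raise SummaryDataError(
                    f"asymmetric LD matrix: ({a},{b}) given as both {self._r2[key]} and {r2}"
                )
            self._r2[key] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (min(a, b), max(a, b))
        if key not in self._r2:
            self.missing_pairs.append(key)
            return 0.0
        return self._r2[key]

    @classmethod
    def from_table(cls, path) -> "LdMatrix":
        """Read a 3-column TSV (snp_a, snp_b, r2)."""
        df = pd.read_csv(path, sep="\t", comment="#")
        need = {"snp_a", "snp_b", "r2"}
        if not need.issubset(df.columns):
            raise SummaryDataError(f"LD table must have columns {sorted(need)}, got {list(df.columns)}")
        return cls({(r.snp_a, r.snp_b): float(r.r2) for r in df.itertuples()})

    @classmethod
    def from_square(cls, path) -> "LdMatrix":
        """Read a square matrix with rsID header and index."""
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if list(df.index) != list(df.columns):
            raise SummaryDataError("square LD matrix must have identical row/column rsIDs")
        arr = df.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise SummaryDataError("square LD matrix is not symmetric")
        if not np.allclose(np.diag(arr), 1.0, atol=1e-9):
            raise SummaryDataError("square LD matrix diagonal must be 1")
        ids = list(df.index)
        return cls(
            {
                (ids[i], ids[j]): arr[i, j]
                for i in range(len(ids))
                for j in range(i + 1, len(ids))
            }
        )


def read_summary_table(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    return_log: bool = False,
):
    """Read a TSV of GWAS summary statistics into :class:`GwasRecord` rows.

    Parameters
    ----------
    path
        TSV file with a header line; ``#``-prefixed lines are comments.
    dialect
        Mapping from canonical field names (``snp_id``, ``beta``, ...) to the
        column names used in the file. Unmapped fields use the defaults.
    return_log
        Also return a list of ``(line, rule, detail)`` entries for rejected
        rows (non-positive SE, unparsable numerics).

    P-values printed beyond float range (e.g. 1e-610) underflow to zero on
    parse; they are clamped to the smallest positive normal float so the
    strict significance inequality still retains them.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for key in _MANDATORY:
        if cols[key] not in df.columns:
            raise SummaryDataError(f"missing mandatory column '{cols[key]}' (field {key})")
    records: list[GwasRecord] = []
    log: list[tuple[int, str, str]] = []
    tiny = float(np.finfo(float).tiny)
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            pval = float(row[cols["pval"]])
            if pval == 0.0:
                pval = tiny
            rec = GwasRecord(
                snp_id=str(row[cols["snp_id"]]),
                effect_allele=str(row[cols["effect_allele"]]),
                other_allele=str(row[cols["other_allele"]]),
                eaf=float(row[cols["eaf"]]),
                beta=float(row[cols["beta"]]),
                se=float(row[cols["se"]]),
                pval=pval,
                chrom=str(row[cols["chrom"]]) if cols["chrom"] in df.columns else "",
                pos=int(float(row[cols["pos"]])) if cols["pos"] in df.columns else 0,
                n=int(float(row[cols["n"]]))
                if cols["n"] in df.columns and pd.notna(row[cols["n"]])
                else None,
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, SummaryDataError):
                log.append((line, "invalid_record", str(exc)))
                continue
            raise SummaryDataError(f"line {line}: unparsable numeric value ({exc})") from exc
        records.append(rec)
    if return_log:
        return records, log
    return records


def select_instruments(
    records: Sequence[GwasRecord], p_threshold: float = 5e-8
) -> list[GwasRecord]:
    """Keep records with ``pval`` strictly below the significance threshold."""
    if not 0.0 < p_threshold <= 1.0:
        raise SummaryDataError(f"p_threshold must lie in (0, 1], got {p_threshold}")
    return [r for r in records if r.pval < p_threshold]


def ld_prune(
    records: Sequence[GwasRecord],
    r2_matrix: LdMatrix,
    r2_threshold: float = 0.01,
    *,
    log: list[tuple[str, str, str]] | None = None,
) -> list[GwasRecord]:
    """Greedy LD clumping: keep the most significant variant of each clump.

    Records are visited in ascending p-value order; a variant is dropped if
    its r² with any already-kept variant reaches ``r2_threshold``.
    """
    order = sorted(records, key=lambda r: (r.pval, r.snp_id))
    kept: list[GwasRecord] = []
    for rec in order:
        clash = next(
            (k for k in kept if r2_matrix.r2(rec.snp_id, k.snp_id) >= r2_threshold), None
        )
        if clash is None:
            kept.append(rec)
        elif log is not None:
            log.append(
                (
                    rec.snp_id,
                    "ld_prune",
                    f"r2 with {clash.snp_id} >= {r2_threshold}",
                )
            )
    kept_ids = {k.snp_id for k in kept}
    return [r for r in records if r.snp_id in kept_ids]


def find_proxy(
    target: str,
    outcome_records: Sequence[GwasRecord],
    r2_matrix: LdMatrix,
    r2_min: float = 0.8,
) -> GwasRecord | None:
    """Best LD proxy for ``target`` among the outcome records.

    Returns the record with maximal r² to the target among candidates with
    r² strictly above ``r2_min``; ties break by smaller p-value, then
    lexicographic rsID. ``None`` when no candidate qualifies.
    """
    best: GwasRecord | None = None
    best_key: tuple[float, float, str] | None = None
    for rec in outcome_records:
        r2 = r2_matrix.r2(target, rec.snp_id)
        if r2 <= r2_min:
            continue
        key = (-r2, rec.pval, rec.snp_id)
        if best_key is None or key < best_key:
            best, best_key = rec, key
    return best


def is_palindromic(record: GwasRecord) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G}).

    Multi-base (indel) alleles are never palindromic.
    """
    a, b = record.effect_allele, record.other_allele
    if len(a) != 1 or len(b) != 1:
        return False
    return {a, b} in ({"A", "T"}, {"C", "G"})


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


def harmonise(
    exposure: GwasRecord,
    outcome: GwasRecord,
    drop_palindromic: bool = True,
    *,
    proxy_of: str = "",
    log: list[tuple[str, str, str]] | None = None,
) -> HarmonisedInstrument | None:
    """Align an exposure/outcome record pair to the exposure's effect allele.

    Rules, in order:

    * palindromic exposure variants are dropped when ``drop_palindromic``
      (their strand cannot be resolved from alleles alone);
    * outcome alleles equal to the exposure alleles: copy the outcome beta;
    * outcome alleles swapped: negate the outcome beta and flip its EAF;
    * outcome alleles matching only under strand complement: complement,
      then apply the two rules above;
    * anything else is incompatible and yields ``None`` with a log entry.
    """
    if drop_palindromic and is_palindromic(exposure):
        if log is not None:
            log.append((exposure.snp_id, "palindromic", f"{exposure.effect_allele}/{exposure.other_allele}"))
        return None

    ea_x, oa_x = exposure.effect_allele, exposure.other_allele
    ea_y, oa_y = outcome.effect_allele, outcome.other_allele

    def build(beta_y: float, eaf_y: float) -> HarmonisedInstrument:
        return HarmonisedInstrument(
            snp_id=exposure.snp_id,
            beta_x=exposure.beta,
            se_x=exposure.se,
            beta_y=beta_y,
            se_y=outcome.se,
            eaf_x=exposure.eaf,
            eaf_y=eaf_y,
            f_stat=f_statistic(exposure),
            proxy_of=proxy_of,
        )

    if (ea_y, oa_y) == (ea_x, oa_x):
        return build(outcome.beta, outcome.eaf)
    if (ea_y, oa_y) == (oa_x, ea_x):
        return build(-outcome.beta, 1.0 - outcome.eaf)
    cea, coa = _complement(ea_y), _complement(oa_y)
    if cea is not None and coa is not None:
        if (cea, coa) == (ea_x, oa_x):
            return build(outcome.beta, outcome.eaf)
        if (cea, coa) == (oa_x, ea_x):
            return build(-outcome.beta, 1.0 - outcome.eaf)
    if log is not None:
        log.append(
            (
                exposure.snp_id,
                "incompatible_alleles",
                f"exposure {ea_x}/{oa_x} vs outcome {ea_y}/{oa_y}",
            )
        )
    return None


def f_statistic(
    record: GwasRecord, method: str = "ratio", n: int | None = None
) -> float:
    """Instrument-strength F statistic for a single variant.

    ``method='ratio'`` (default) uses the summary-data approximation
    F = (beta/se)². ``method='r2'`` uses F = R²(n−2)/(1−R²) with
    R² = 2·EAF(1−EAF)·beta², requiring a sample size.
    """
    if method == "ratio":
        return (record.beta / record.se) ** 2
    if method == "r2":
        n_eff = n if n is not None else record.n
        if n_eff is None:
            raise SummaryDataError(f"{record.snp_id}: sample size required for R2-based F")
        r2 = 2.0 * record.eaf * (1.0 - record.eaf) * record.beta**2
        if r2 >= 1.0:
            raise SummaryDataError(f"{record.snp_id}: implied R2 >= 1")
        return r2 * (n_eff - 2) / (1.0 - r2)
    raise SummaryDataError(f"unknown F-statistic method '{method}'")


def filter_weak(
    instruments: Iterable[HarmonisedInstrument],
    f_min: float = 10.0,
    exposure_name: str = "",
) -> InstrumentSet:
    """Drop weak instruments (F below ``f_min``) into an audited set."""
    out = InstrumentSet(exposure_name=exposure_name, instruments=[])
    for inst in instruments:
        if inst.f_stat < f_min:
            out.log(inst.snp_id, "weak_instrument", f"F={inst.f_stat:.3g} < {f_min}")
        else:
            out.instruments.append(inst)
    return out
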