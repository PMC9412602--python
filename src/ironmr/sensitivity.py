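"""Heterogeneity, pleiotropy and influence diagnostics for instrument sets.

* :func:`cochran_q` — Cochran's Q over the per-SNP Wald ratios; excess Q
  flags instruments whose ratio estimates disagree beyond chance.
* :func:`leave_one_out` — IVW refit excluding each instrument in turn, to
  detect results driven by a single SNP.
* :func:`funnel_data` — per-SNP (ratio, precision) pairs for funnel-plot
  inspection of directional asymmetry; exported as a table rather than a
  figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mr_core import IVW, MRError, MRResults, wald_ratio
from .summary_data import HarmonisedInstrument

__all__ = ["HeterogeneityResult", "LeaveOneOutResult", "FunnelPoint",
           "cochran_q", "leave_one_out", "funnel_data"]


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    pval: float
    per_snp_q: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"q": self.q, "df": self.df, "pval": self.pval}])


@dataclass(frozen=True)
class LeaveOneOutResult:
    """One IVW row per excluded SNP plus the all-SNP row (excluded_snp='')."""

    rows: tuple[tuple[str, float, float, float], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["excluded_snp", "theta", "se", "pval"])


@dataclass(frozen=True)
class FunnelPoint:
    snp_id: str
    theta: float
    precision: float


def cochran_q(instruments: Sequence[HarmonisedInstrument]) -> HeterogeneityResult:
    """Cochran's Q with fixed-effect IVW weights.

    q_j = w_j (theta_j − theta_IVW)² with first-order weights w_j fixed at
    their full-set values; the p-value is the upper tail of chi-square with
    J−1 degrees of freedom.
    """
    if len(instruments) < 2:
        raise MRError("Cochran's Q needs at least 2 instruments")
    ratios = [wald_ratio(i) for i in instruments]
    theta_j = np.array([r.theta for r in ratios])
    w = np.array([r.weight for r in ratios])
    theta = float(np.sum(w * theta_j) / np.sum(w))
    per = w * (theta_j - theta) ** 2
    q = float(np.sum(per))
    df = len(ratios) - 1
    return HeterogeneityResult(
        q=q,
        df=df,
        pval=float(stats.chi2.sf(q, df)),
        per_snp_q={r.snp_id: float(p) for r, p in zip(ratios, per)},
    )


def leave_one_out(instruments: Sequence[HarmonisedInstrument]) -> LeaveOneOutResult:
    """IVW refits each excluding one SNP, plus the full-set fit.

    With J = 2 the reduced fits collapse to single-SNP Wald ratios, which is
    permitted.
    """
    if len(instruments) < 2:
        raise MRError("leave-one-out needs at least 2 instruments")

    def row(excluded: str, res: MRResults) -> tuple[str, float, float, float]:
        return (excluded, res.theta, res.se, res.pval)

    rows = [
        row(inst.snp_id, IVW([j for j in instruments if j is not inst]).fit())
        for inst in instruments
    ]
    rows.append(row("", IVW(instruments).fit()))
    return LeaveOneOutResult(rows=tuple(rows))


def funnel_data(instruments: Sequence[HarmonisedInstrument]) -> list[FunnelPoint]:
    """Per-SNP (Wald ratio, precision = 1/se) points for funnel inspection."""
    if not instruments:
        raise MRError("funnel data needs at least 1 instrument")
    out = []
    for inst in instruments:
        r = wald_ratio(inst)
        out.append(FunnelPoint(snp_id=r.snp_id, theta=r.theta, precision=1.0 / r.se_theta))
    return out
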