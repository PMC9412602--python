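"""Causal-effect estimators for two-sample Mendelian randomisation.

Given J harmonised instruments with SNP-exposure effects ``beta_x`` (SE
``se_x``) and SNP-outcome effects ``beta_y`` (SE ``se_y``), the per-SNP Wald
ratio theta_j = beta_y_j / beta_x_j estimates the causal effect of the
exposure on the outcome under the instrumental-variable assumptions. This
module pools the ratios:

* :class:`IVW` — inverse-variance-weighted mean (fixed- or
  multiplicative-random-effect standard errors);
* :class:`MREgger` — weighted regression of beta_y on beta_x with an
  unconstrained intercept; a non-zero intercept indicates average
  directional pleiotropy;
* :class:`WeightedMedian` — weighted median of the ratio estimates,
  consistent when instruments carrying more than half of the weight are
  valid; its SE comes from a parametric bootstrap.

Each model is constructed from a list of
:class:`~ironmr.summary_data.HarmonisedInstrument` and its ``fit()`` returns
a results object with the estimate, its uncertainty, the odds-ratio
transform and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .summary_data import HarmonisedInstrument

__all__ = [
    "RatioEstimate",
    "MRResults",
    "EggerResults",
    "IVW",
    "MREgger",
    "WeightedMedian",
    "wald_ratio",
    "to_odds_ratio",
]


class MRError(ValueError):
    """Raised for invalid estimator inputs (e.g. too few instruments)."""


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with its delta-method SE and IVW weight."""

    snp_id: str
    theta: float
    se_theta: float

    @property
    def weight(self) -> float:
        return self.se_theta**-2


def wald_ratio(inst: HarmonisedInstrument, order: str = "first") -> RatioEstimate:
    """Wald ratio theta = beta_y/beta_x with delta-method standard error.

    ``order='first'`` gives se = se_y/|beta_x| (the convention of the
    standard two-sample toolchains); ``order='second'`` adds the
    contribution of the exposure uncertainty,
    se² = se_y²/beta_x² + beta_y²·se_x²/beta_x⁴.
    """
    if inst.beta_x == 0:
        raise MRError(f"{inst.snp_id}: beta_x = 0, Wald ratio undefined")
    theta = inst.beta_y / inst.beta_x
    if order == "first":
        se = inst.se_y / abs(inst.beta_x)
    elif order == "second":
        se = np.sqrt(
            inst.se_y**2 / inst.beta_x**2
            + inst.beta_y**2 * inst.se_x**2 / inst.beta_x**4
        )
    else:
        raise MRError(f"unknown delta-method order '{order}'")
    return RatioEstimate(snp_id=inst.snp_id, theta=theta, se_theta=se)


def _z_for(ci_level: float) -> float:
    return float(stats.norm.ppf(0.5 + ci_level / 2.0))


@dataclass(frozen=True)
class MRResults:
    """A pooled causal-effect estimate on the log-odds (or linear) scale."""

    method: str
    theta: float
    se: float
    pval: float
    n_snp: int
    exposure: str = ""
    outcome: str = ""

    @property
    def or_point(self) -> float:
        return float(np.exp(self.theta))

    def odds_ratio(self, ci_level: float = 0.95) -> tuple[float, float, float]:
        """(OR, lower, upper) at the requested CI coverage."""
        z = _z_for(ci_level)
        return (
            float(np.exp(self.theta)),
            float(np.exp(self.theta - z * self.se)),
            float(np.exp(self.theta + z * self.se)),
        )

    def conf_int(self, ci_level: float = 0.95) -> tuple[float, float]:
        z = _z_for(ci_level)
        return (self.theta - z * self.se, self.theta + z * self.se)

    def summary(self, ci_level: float = 0.95) -> pd.DataFrame:
        or_point, or_low, or_high = self.odds_ratio(ci_level)
        return pd.DataFrame(
            [
                {
                    "method": self.method,
                    "exposure": self.exposure,
                    "outcome": self.outcome,
                    "n_snp": self.n_snp,
                    "theta": self.theta,
                    "se": self.se,
                    "pval": self.pval,
                    "or": or_point,
                    "or_low": or_low,
                    "or_high": or_high,
                }
            ]
        )


def to_odds_ratio(est: MRResults, ci_level: float = 0.95) -> MRResults:
    """Return ``est`` unchanged (ORs are a view); kept for pipeline symmetry.

    The odds-ratio transform exp(theta ± z·se) is exposed as
    :meth:`MRResults.odds_ratio`; this function validates the input and
    returns the same results object so callers can treat the transform as a
    pipeline stage.
    """
    if est.se <= 0:
        raise MRError("standard error must be positive")
    est.odds_ratio(ci_level)
    return est


class _InstrumentModel:
    """Shared validation for models built from harmonised instruments."""

    min_snps = 1

    def __init__(
        self,
        instruments: Sequence[HarmonisedInstrument],
        exposure: str = "",
        outcome: str = "",
    ):
        if len(instruments) < self.min_snps:
            raise MRError(
                f"{type(self).__name__} needs at least {self.min_snps} instruments, "
                f"got {len(instruments)}"
            )
        self.instruments = list(instruments)
        self.exposure = exposure
        self.outcome = outcome
        self.beta_x = np.array([i.beta_x for i in instruments], dtype=float)
        self.se_x = np.array([i.se_x for i in instruments], dtype=float)
        self.beta_y = np.array([i.beta_y for i in instruments], dtype=float)
        self.se_y = np.array([i.se_y for i in instruments], dtype=float)


class IVW(_InstrumentModel):
    """Inverse-variance-weighted pooled Wald ratio.

    Parameters
    ----------
    instruments
        Harmonised instruments (beta_x must be non-zero for all).
    model
        ``'fixed'`` (default): se = (sum of weights)^-1/2.
        ``'random'``: multiplicative random-effect model; the fixed-effect
        SE is inflated by max(1, sqrt(Q/(J-1))).
    order
        Delta-method order for the per-SNP SEs (see :func:`wald_ratio`).
    """

    def __init__(self, instruments, model: str = "fixed", order: str = "first", **kw):
        super().__init__(instruments, **kw)
        if model not in ("fixed", "random"):
            raise MRError(f"unknown IVW model '{model}'")
        self.model = model
        self.order = order

    def fit(self) -> MRResults:
        ratios = [wald_ratio(i, order=self.order) for i in self.instruments]
        theta_j = np.array([r.theta for r in ratios])
        w = np.array([r.weight for r in ratios])
        theta = float(np.sum(w * theta_j) / np.sum(w))
        se = float(np.sum(w) ** -0.5)
        method = f"ivw_{self.model}"
        if self.model == "random" and len(ratios) > 1:
            q = float(np.sum(w * (theta_j - theta) ** 2))
            se *= max(1.0, np.sqrt(q / (len(ratios) - 1)))
        pval = float(2.0 * stats.norm.sf(abs(theta / se)))
        if len(ratios) == 1:
            method = "wald"
        return MRResults(
            method=method,
            theta=theta,
            se=se,
            pval=pval,
            n_snp=len(ratios),
            exposure=self.exposure,
            outcome=self.outcome,
        )


@dataclass(frozen=True)
class EggerResults:
    """MR-Egger slope (causal estimate) and intercept (directional pleiotropy)."""

    slope: float
    se_slope: float
    p_slope: float
    intercept: float
    se_intercept: float
    p_intercept: float
    df: int
    n_snp: int
    exposure: str = ""
    outcome: str = ""

    def as_mr_results(self) -> MRResults:
        return MRResults(
            method="egger",
            theta=self.slope,
            se=self.se_slope,
            pval=self.p_slope,
            n_snp=self.n_snp,
            exposure=self.exposure,
            outcome=self.outcome,
        )

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"term": "slope", "estimate": self.slope, "se": self.se_slope, "pval": self.p_slope},
                {
                    "term": "intercept",
                    "estimate": self.intercept,
                    "se": self.se_intercept,
                    "pval": self.p_intercept,
                },
            ]
        ).assign(df=self.df, exposure=self.exposure, outcome=self.outcome)


class MREgger(_InstrumentModel):
    """MR-Egger regression: beta_y on beta_x with intercept, weights 1/se_y².

    Instruments are first oriented so every beta_x is non-negative (the
    standard Egger convention; jointly negating a beta pair is an allele
    recode, which leaves the causal slope meaningful while giving the
    intercept a definite sign). Inference uses a t distribution with J-2
    degrees of freedom and a multiplicative residual scale, matching the
    behaviour of weighted least squares in standard toolchains.
    """

    min_snps = 3

    def fit(self) -> EggerResults:
        sign = np.where(self.beta_x < 0, -1.0, 1.0)
        bx = self.beta_x * sign
        by = self.beta_y * sign
        w = self.se_y**-2
        X = sm.add_constant(bx)
        res = sm.WLS(by, X, weights=w).fit()
        df = len(bx) - 2
        return EggerResults(
            slope=float(res.params[1]),
            se_slope=float(res.bse[1]),
            p_slope=float(res.pvalues[1]),
            intercept=float(res.params[0]),
            se_intercept=float(res.bse[0]),
            p_intercept=float(res.pvalues[0]),
            df=df,
            n_snp=len(bx),
            exposure=self.exposure,
            outcome=self.outcome,
        )


class WeightedMedian(_InstrumentModel):
    """Weighted median of the per-SNP Wald ratios.

    The point estimate interpolates the weighted empirical distribution of
    ratio estimates at cumulative weight 0.5: with ratios sorted ascending
    and normalised weights p_j, the cumulative midpoints are
    s_j = sum_{i<=j} p_i − p_j/2 and the estimate is the linear
    interpolation of theta at s = 0.5. The SE is the standard deviation of
    the estimator over ``n_boot`` parametric-bootstrap replicates in which
    beta_x and beta_y are redrawn from normal distributions centred on the
    observed values with the reported SEs.
    """

    min_snps = 3

    def __init__(self, instruments, n_boot: int = 5000, seed: int | None = None, **kw):
        super().__init__(instruments, **kw)
        if n_boot < 1:
            raise MRError("n_boot must be >= 1")
        if seed is None:
            raise MRError("WeightedMedian requires an explicit RNG seed")
        self.n_boot = n_boot
        self.seed = seed

    @staticmethod
    def _weighted_median(theta: np.ndarray, weight: np.ndarray) -> float:
        order = np.argsort(theta)
        theta = theta[order]
        p = weight[order] / weight.sum()
        s = np.cumsum(p) - p / 2.0
        return float(np.interp(0.5, s, theta))

    def fit(self) -> MRResults:
        ratios = [wald_ratio(i) for i in self.instruments]
        theta_j = np.array([r.theta for r in ratios])
        w = np.array([r.weight for r in ratios])
        point = self._weighted_median(theta_j, w)

        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bx = rng.normal(self.beta_x, self.se_x)
            by = rng.normal(self.beta_y, self.se_y)
            bx = np.where(bx == 0, np.finfo(float).tiny, bx)
            th = by / bx
            wb = (self.se_y / np.abs(bx)) ** -2
            boots[b] = self._weighted_median(th, wb)
        se = float(np.std(boots, ddof=1)) if self.n_boot > 1 else float("nan")
        pval = float(2.0 * stats.norm.sf(abs(point / se))) if se > 0 else 1.0
        return MRResults(
            method="weighted_median",
            theta=point,
            se=se,
            pval=pval,
            n_snp=len(ratios),
            exposure=self.exposure,
            outcome=self.outcome,
        )
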