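"""Multivariable Mendelian randomisation by inverse-variance weighting.

A single weighted regression of the SNP-outcome effects on the J x K matrix
of SNP-exposure effects (weights 1/se_y², no intercept) estimates the
*direct* effect of each exposure conditional on the others. Collinear
exposures make these direct effects unidentifiable, so the model reports a
condition number and per-exposure variance-inflation factors and refuses a
rank-deficient design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .mr_bma import BmaInput

__all__ = ["MVMR", "MVMRResults", "CollinearityError"]


class CollinearityError(ValueError):
    """Raised when the exposure design is (numerically) rank deficient."""


@dataclass(frozen=True)
class MVMRResults:
    """Direct-effect estimates with conditioning diagnostics."""

    exposures: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    n_snp: int
    condition_number: float
    vif: np.ndarray | None

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "exposure": self.exposures,
                "n_snp": self.n_snp,
                "beta": self.beta,
                "se": self.se,
                "pval": self.pval,
            }
        )
        if self.vif is not None:
            df["vif"] = self.vif
        df["condition_number"] = self.condition_number
        return df


class MVMR:
    """Multivariable IVW model over a :class:`~ironmr.mr_bma.BmaInput`.

    ``fit()`` runs weighted least squares of beta_y on the K exposure
    columns with weights 1/se_y² and no intercept; SEs follow the weighted
    normal equations with estimated residual scale, and p-values use a t
    distribution with J−K degrees of freedom.
    """

    def __init__(self, input: BmaInput, rank_rtol: float = 1e-10):
        if input.n_snp <= input.n_factor:
            raise ValueError(
                f"need more instruments than exposures, got J={input.n_snp}, K={input.n_factor}"
            )
        if np.any(np.all(input.beta_x == 0, axis=0)):
            dead = [
                n for n, col in zip(input.factor_names, input.beta_x.T) if not col.any()
            ]
            raise ValueError(f"all-zero exposure column(s): {dead}")
        self.input = input
        self.rank_rtol = rank_rtol

    def _weighted_design(self) -> tuple[np.ndarray, np.ndarray]:
        Xt, yt = self.input.weighted()
        return Xt, yt

    def _check_rank(self, Xt: np.ndarray) -> None:
        rank = np.linalg.matrix_rank(Xt, tol=self.rank_rtol * np.linalg.norm(Xt, 2))
        if rank < Xt.shape[1]:
            # name the columns involved in exact linear dependence
            corr = np.corrcoef(Xt, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            pairs = [
                (self.input.factor_names[i], self.input.factor_names[j])
                for i in range(corr.shape[0])
                for j in range(i + 1, corr.shape[1])
                if abs(corr[i, j]) > 1.0 - 1e-9
            ]
            raise CollinearityError(
                f"rank-deficient exposure design (rank {rank} < {Xt.shape[1]}); "
                f"collinear pairs: {pairs or 'non-pairwise dependence'}"
            )

    def fit(self) -> MVMRResults:
        Xt, yt = self._weighted_design()
        self._check_rank(Xt)
        res = sm.OLS(yt, Xt).fit()  # rows already carry the 1/se_y weights
        cond, vif = self.collinearity_check(require_multiple=False)
        return MVMRResults(
            exposures=self.input.factor_names,
            beta=np.asarray(res.params, dtype=float),
            se=np.asarray(res.bse, dtype=float),
            pval=np.asarray(res.pvalues, dtype=float),
            n_snp=self.input.n_snp,
            condition_number=cond,
            vif=vif,
        )

    def collinearity_check(
        self, require_multiple: bool = True
    ) -> tuple[float, np.ndarray | None]:
        """(condition number of the weighted design, per-exposure VIFs).

        VIFs need K >= 2 exposures; with one exposure ``None`` is returned
        (or an error if ``require_multiple``).
        """
        Xt, _ = self._weighted_design()
        sv = np.linalg.svd(Xt, compute_uv=False)
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
        if self.input.n_factor < 2:
            if require_multiple:
                raise ValueError("VIF needs at least 2 exposures")
            return cond, None
        vif = np.array(
            [variance_inflation_factor(Xt, k) for k in range(Xt.shape[1])]
        )
        return cond, vif
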