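"""Bayesian-model-averaged multivariable Mendelian randomisation (MR-BMA).

With K candidate risk factors measured on the same J instruments, each
non-empty subset S of factors defines a multivariable MR model. Working on
the inverse-variance-weighted scale (each instrument row divided by the
outcome SE, x_tilde = beta_x/se_y, y_tilde = beta_y/se_y), a model's
marginal likelihood is available in closed form under a zero-centred normal
prior on the causal effects:

    y_tilde | S ~ Normal(0, I_J + sigma^2 * X_S X_S^T)

with prior model probability prior_prob^|S| (1-prior_prob)^(K-|S|). Posterior
model probabilities (PP) are normalised over the enumerated model space; a
factor's marginal inclusion probability (MIP) is the sum of the PPs of all
models containing it, and its model-averaged causal effect (MACE) is the
PP-weighted average of its ridge posterior-mean estimates.

Diagnostics on the highest-PP model follow the applied convention: the
per-variant Q statistic is the squared residual on the weighted scale, and
Cook's distance measures each instrument's influence on the model fit.
:meth:`MRBMA.fit_with_exclusion` implements the iterative clean-up used in
applied work: repeatedly drop the worst instrument whose Q exceeds a
cut-off, then the worst whose Cook's distance exceeds a threshold,
re-fitting after each removal.

Exposure columns are weighted by 1/se_y only; they are not re-standardised,
so users comparing against implementations that scale risk-factor columns
should scale their inputs first (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["BmaInput", "BmaModel", "BMAResults", "VariantDiagnostics", "MRBMA",
           "enumerate_models"]


class BmaError(ValueError):
    """Raised for invalid MR-BMA inputs (dimensions, collinearity)."""


@dataclass(frozen=True)
class BmaInput:
    """J instruments × K risk factors of SNP-exposure effects plus outcome.

    ``se_x`` is carried for provenance/simulation but does not enter the
    likelihood (the weighting is by outcome SE only).
    """

    beta_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    factor_names: tuple[str, ...]
    snp_ids: tuple[str, ...]
    se_x: np.ndarray | None = None

    def __post_init__(self) -> None:
        bx = np.asarray(self.beta_x, dtype=float)
        by = np.asarray(self.beta_y, dtype=float)
        sy = np.asarray(self.se_y, dtype=float)
        if bx.ndim != 2:
            raise BmaError("beta_x must be a J x K matrix")
        j, k = bx.shape
        if by.shape != (j,) or sy.shape != (j,):
            raise BmaError("beta_y and se_y must be length-J vectors")
        if k < 1 or j < k:
            raise BmaError(f"need J >= K >= 1, got J={j}, K={k}")
        if np.any(sy <= 0):
            raise BmaError("all outcome SEs must be positive")
        if len(self.factor_names) != k or len(self.snp_ids) != j:
            raise BmaError("factor_names/snp_ids lengths must match beta_x shape")
        object.__setattr__(self, "beta_x", bx)
        object.__setattr__(self, "beta_y", by)
        object.__setattr__(self, "se_y", sy)

    @property
    def n_snp(self) -> int:
        return self.beta_x.shape[0]

    @property
    def n_factor(self) -> int:
        return self.beta_x.shape[1]

    def weighted(self) -> tuple[np.ndarray, np.ndarray]:
        """(X_tilde, y_tilde): rows divided by the outcome SE."""
        return self.beta_x / self.se_y[:, None], self.beta_y / self.se_y

    def drop_snps(self, snp_ids: Sequence[str]) -> "BmaInput":
        keep = [i for i, s in enumerate(self.snp_ids) if s not in set(snp_ids)]
        return replace(
            self,
            beta_x=self.beta_x[keep],
            beta_y=self.beta_y[keep],
            se_y=self.se_y[keep],
            snp_ids=tuple(self.snp_ids[i] for i in keep),
            se_x=self.se_x[keep] if self.se_x is not None else None,
        )


@dataclass(frozen=True)
class BmaModel:
    """One factor subset with its evidence and conditional estimates."""

    subset: tuple[int, ...]
    log_marginal: float
    pp: float
    theta_lambda: tuple[float, ...]


@dataclass(frozen=True)
class VariantDiagnostics:
    snp_id: str
    q_stat: float
    cooks_d: float


def enumerate_models(k: int, max_size: int | None = None) -> list[tuple[int, ...]]:
    """All non-empty factor subsets of size <= max_size, ordered by size then
    lexicographically."""
    if k < 1:
        raise BmaError("k must be >= 1")
    cap = k if max_size is None else max_size
    if not 1 <= cap <= k:
        raise BmaError(f"max_size must lie in [1, {k}], got {cap}")
    out: list[tuple[int, ...]] = []
    for size in range(1, cap + 1):
        out.extend(combinations(range(k), size))
    return out


def _log_marginal(Xs: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """log N(y; 0, I + sigma^2 Xs Xs^T) via the Woodbury identity.

    Only |S| x |S| systems are solved, so the cost is independent of J
    beyond the matrix products.
    """
    j, p = Xs.shape
    gram = Xs.T @ Xs
    inner = np.eye(p) + sigma**2 * gram
    sign, logdet_inner = np.linalg.slogdet(inner)
    if sign <= 0:
        raise BmaError("non-positive-definite prior covariance (collinear factors?)")
    xty = Xs.T @ y
    quad = y @ y - sigma**2 * xty @ np.linalg.solve(inner, xty)
    return float(-0.5 * (j * np.log(2.0 * np.pi) + logdet_inner + quad))


def _ridge_mean(Xs: np.ndarray, y: np.ndarray, sigma: float) -> np.ndarray:
    p = Xs.shape[1]
    lhs = Xs.T @ Xs + np.eye(p) / sigma**2
    try:
        return np.linalg.solve(lhs, Xs.T @ y)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by prior
        raise BmaError(f"singular system for subset: {exc}") from exc


@dataclass(frozen=True)
class BMAResults:
    """Posterior summary of the enumerated model space."""

    input: BmaInput
    models: tuple[BmaModel, ...]          # ranked by descending pp
    mip: np.ndarray                       # per-factor marginal inclusion prob
    mace: np.ndarray                      # per-factor model-averaged effect
    prior_prob: float
    sigma: float
    perm_p: np.ndarray | None = None

    @property
    def factor_names(self) -> tuple[str, ...]:
        return self.input.factor_names

    @property
    def rank_by_mip(self) -> np.ndarray:
        order = np.argsort(-self.mip, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(order) + 1)
        return ranks

    @property
    def rank_by_pp(self) -> np.ndarray:
        """Rank factors by the PP of their best single-factor-containing model."""
        best_pp = np.zeros(self.input.n_factor)
        for m in self.models:
            for k in m.subset:
                best_pp[k] = max(best_pp[k], m.pp)
        order = np.argsort(-best_pp, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(1, len(order) + 1)
        return ranks

    @property
    def best_model(self) -> BmaModel:
        return self.models[0]

    def best_models(self, pp_threshold: float = 0.02) -> list[BmaModel]:
        return [m for m in self.models if m.pp >= pp_threshold]

    def theta_best(self, k: int) -> float:
        """Causal estimate of factor k in its best-supported model (0 if absent)."""
        for m in self.models:
            if k in m.subset:
                return m.theta_lambda[m.subset.index(k)]
        return 0.0

    def summary(self, pp_threshold: float = 0.02) -> pd.DataFrame:
        """Per-factor table: MIP/MACE ranking plus best-model PP and estimate."""
        best_pp = np.zeros(self.input.n_factor)
        for m in self.models:
            for k in m.subset:
                best_pp[k] = max(best_pp[k], m.pp)
        rows = []
        for k, name in enumerate(self.factor_names):
            rows.append(
                {
                    "factor": name,
                    "rank_by_mip": int(self.rank_by_mip[k]),
                    "mip": float(self.mip[k]),
                    "mace": float(self.mace[k]),
                    "rank_by_pp": int(self.rank_by_pp[k]),
                    "pp_best": float(best_pp[k]),
                    "theta_best": float(self.theta_best(k)),
                    "perm_p": float(self.perm_p[k]) if self.perm_p is not None else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def variant_diagnostics(self, subset: tuple[int, ...] | None = None) -> list[VariantDiagnostics]:
        """Per-variant Q and Cook's distance under the best (or given) model.

        Q_j is the squared residual (y_tilde_j − x_tilde_j·theta)² of the
        model's ridge fit on the weighted scale; Cook's distance comes from
        the unpenalised weighted regression on the same subset.
        """
        S = self.best_model.subset if subset is None else subset
        if not S:
            raise BmaError("diagnostic subset must be non-empty")
        Xt, yt = self.input.weighted()
        Xs = Xt[:, S]
        theta = _ridge_mean(Xs, yt, self.sigma)
        resid = yt - Xs @ theta
        q = resid**2
        ols = sm.OLS(yt, Xs).fit()
        cooks = ols.get_influence().cooks_distance[0]
        return [
            VariantDiagnostics(snp_id=s, q_stat=float(qj), cooks_d=float(cj))
            for s, qj, cj in zip(self.input.snp_ids, q, cooks)
        ]

    def diagnostics_frame(self, subset: tuple[int, ...] | None = None) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"snp_id": d.snp_id, "q_stat": d.q_stat, "cooks_d": d.cooks_d}
                for d in self.variant_diagnostics(subset)
            ]
        )


class MRBMA:
    """Bayesian model averaging over risk-factor subsets.

    Parameters
    ----------
    input
        A :class:`BmaInput` with the J x K exposure-effect matrix and the
        outcome effects/SEs.
    prior_prob
        Prior probability that any one factor is causal (default 0.1).
    sigma
        Prior SD of a causal effect on the weighted scale (default 0.5).
    max_size
        Optional cap on model size; default enumerates all non-empty subsets.
    """

    def __init__(
        self,
        input: BmaInput,
        prior_prob: float = 0.1,
        sigma: float = 0.5,
        max_size: int | None = None,
    ):
        if not 0.0 < prior_prob < 1.0:
            raise BmaError("prior_prob must lie in (0, 1)")
        if sigma <= 0:
            raise BmaError("sigma must be positive")
        self.input = input
        self.prior_prob = prior_prob
        self.sigma = sigma
        self.max_size = max_size

    def _posteriors(self, input: BmaInput) -> tuple[list[tuple[int, ...]], np.ndarray, list[np.ndarray]]:
        Xt, yt = input.weighted()
        subsets = enumerate_models(input.n_factor, self.max_size)
        k = input.n_factor
        log_post = np.empty(len(subsets))
        thetas: list[np.ndarray] = []
        for i, S in enumerate(subsets):
            Xs = Xt[:, S]
            ll = _log_marginal(Xs, yt, self.sigma)
            log_prior = len(S) * np.log(self.prior_prob) + (k - len(S)) * np.log(
                1.0 - self.prior_prob
            )
            log_post[i] = ll + log_prior
            thetas.append(_ridge_mean(Xs, yt, self.sigma))
        pp = np.exp(log_post - log_post.max())
        pp /= pp.sum()
        return subsets, pp, thetas

    def fit(self, input: BmaInput | None = None) -> BMAResults:
        input = self.input if input is None else input
        subsets, pp, thetas = self._posteriors(input)
        k = input.n_factor
        mip = np.zeros(k)
        mace = np.zeros(k)
        models = []
        Xt, yt = input.weighted()
        for S, p, th in zip(subsets, pp, thetas):
            models.append(
                BmaModel(
                    subset=S,
                    log_marginal=_log_marginal(Xt[:, S], yt, self.sigma),
                    pp=float(p),
                    theta_lambda=tuple(float(t) for t in th),
                )
            )
            for pos, kk in enumerate(S):
                mip[kk] += p
                mace[kk] += p * th[pos]
        models.sort(key=lambda m: (-m.pp, m.subset))
        return BMAResults(
            input=input,
            models=tuple(models),
            mip=mip,
            mace=mace,
            prior_prob=self.prior_prob,
            sigma=self.sigma,
        )

    def cooks_threshold(self, subset_size: int, n_snp: int) -> float:
        """Median of the F(|S|, J−|S|) distribution, the conventional cut-off."""
        return float(stats.f.ppf(0.5, subset_size, n_snp - subset_size))

    def fit_with_exclusion(
        self,
        q_max: float = 10.0,
        cooks_threshold: float | None = None,
    ) -> tuple[BMAResults, list[tuple[str, str, float]], list[BMAResults]]:
        """Iterative instrument clean-up.

        Phase 1 (heterogeneity): repeatedly refit and remove the single
        worst instrument whose per-variant Q exceeds ``q_max``. Phase 2
        (influence): likewise for Cook's distance above ``cooks_threshold``
        (default: median of F(|S|, J−|S|)). A stage result is recorded after
        the initial fit and after every removal.

        Returns (final results, exclusion trail [(snp, rule, value)], stage
        results). Stops with the last valid stage if a removal would leave
        fewer instruments than factors + 1.
        """
        input = self.input
        stages: list[BMAResults] = []
        trail: list[tuple[str, str, float]] = []

        def worst(res: BMAResults, attr: str, threshold: float):
            diags = res.variant_diagnostics()
            over = [d for d in diags if getattr(d, attr) > threshold]
            if not over:
                return None
            return max(over, key=lambda d: getattr(d, attr))

        res = self.fit(input)
        stages.append(res)
        for attr, rule in (("q_stat", "q_statistic"), ("cooks_d", "cooks_distance")):
            while True:
                if attr == "q_stat":
                    threshold = q_max
                else:
                    threshold = (
                        cooks_threshold
                        if cooks_threshold is not None
                        else self.cooks_threshold(len(res.best_model.subset), input.n_snp)
                    )
                bad = worst(res, attr, threshold)
                if bad is None:
                    break
                if input.n_snp - 1 < input.n_factor + 1:
                    import warnings

                    warnings.warn(
                        f"stopping exclusion: removing {bad.snp_id} would leave "
                        f"fewer instruments than factors + 1",
                        stacklevel=2,
                    )
                    return res, trail, stages
                input = input.drop_snps([bad.snp_id])
                trail.append((bad.snp_id, rule, getattr(bad, attr)))
                res = self.fit(input)
                stages.append(res)
        return res, trail, stages

    def permutation_pvalues(
        self, n_perm: int = 1000, seed: int | None = None, input: BmaInput | None = None
    ) -> np.ndarray:
        """Permutation p-value per factor for its marginal inclusion probability.

        The outcome rows (beta_y, se_y pairs) are permuted across
        instruments, breaking any exposure-outcome alignment while keeping
        both marginal distributions; p_k is the add-one-smoothed proportion
        of permutations whose MIP_k reaches the observed value.
        """
        if n_perm < 100:
            raise BmaError("n_perm must be >= 100")
        if seed is None:
            raise BmaError("permutation test requires an explicit seed")
        input = self.input if input is None else input
        _, pp, _ = self._posteriors(input)
        subsets = enumerate_models(input.n_factor, self.max_size)
        observed = np.zeros(input.n_factor)
        for S, p in zip(subsets, pp):
            for kk in S:
                observed[kk] += p
        rng = np.random.default_rng(seed)
        count = np.zeros(input.n_factor)
        for _ in range(n_perm):
            perm = rng.permutation(input.n_snp)
            permuted = replace(input, beta_y=input.beta_y[perm], se_y=input.se_y[perm])
            _, pp_b, _ = self._posteriors(permuted)
            mip_b = np.zeros(input.n_factor)
            for S, p in zip(subsets, pp_b):
                for kk in S:
                    mip_b[kk] += p
            count += mip_b >= observed - 1e-15
        return (1.0 + count) / (n_perm + 1.0)
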