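"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of a two-sample MR study: J
independent variants with per-factor exposure effects beta_x drawn from a
zero-centred normal (truncated away from zero so no instrument is
vacuously weak), outcome effects

    gamma_j = sum_k theta_k * beta_x[j, k] + alpha_j

where alpha_j is a direct (pleiotropic) effect on the outcome, and
observed summary statistics drawn around the truth with the stated
measurement SEs. Pleiotropy modes:

* ``none`` — alpha = 0 for every variant (all instruments valid);
* ``balanced`` — a random ``invalid_fraction`` of variants get
  alpha ~ Normal(0, pleiotropy_sd) (InSIDE holds, mean zero);
* ``directional`` — the invalid variants get
  alpha ~ Normal(pleiotropy_mean, pleiotropy_sd) *aligned with the
  exposure-increasing allele* (of the first factor): allele coding is
  arbitrary, so a directional pleiotropic pathway is directional relative
  to the variant's effect on the exposure, not to the coded allele. This
  biases IVW while the weighted median stays consistent as long as valid
  instruments carry more than half the weight.

Tables are emitted in the same TSV dialect :mod:`ironmr.summary_data`
reads, with allele and EAF columns filled consistently between the
exposure and outcome samples, so generated data round-trips through the
full pipeline. A truth record carries every latent value for oracle
checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import table1_fixture  # re-exported packaged fixture
from .summary_data import HarmonisedInstrument

__all__ = ["SyntheticScenario", "generate", "generated_instruments", "table1_fixture"]

# allele pairs that survive the palindrome filter
_SAFE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
               ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for a two-sample summary-statistic study.

    Defaults describe a well-powered null study: 20 independent instruments
    for a single exposure, no causal effect, no pleiotropy, exposure effects
    of SD 0.1 (typical biomarker GWAS scale) measured with SE 0.01 in the
    exposure sample and outcome effects measured with SE 0.01.
    """

    n_snp: int = 20
    k_factors: int = 1
    theta_true: tuple[float, ...] = (0.0,)
    beta_x_scale: float = 0.1
    se_x: float = 0.01
    se_y: float = 0.01
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    invalid_fraction: float = 0.0
    allow_palindromic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode '{self.pleiotropy_mode}'")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must lie in [0, 1]")
        if len(self.theta_true) != self.k_factors:
            raise ValueError("theta_true must have one entry per factor")
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError("measurement SEs must be positive")
        if self.beta_x_scale <= 0:
            raise ValueError("beta_x_scale must be positive")


def _draw_truncated_normal(rng: np.random.Generator, scale: float, size) -> np.ndarray:
    """Normal(0, scale²) resampled until |x| > 0.5*scale (no vacuous instruments)."""
    out = rng.normal(0.0, scale, size=size)
    while True:
        weak = np.abs(out) <= 0.5 * scale
        if not weak.any():
            return out
        out[weak] = rng.normal(0.0, scale, size=int(weak.sum()))


def generate(
    scenario: SyntheticScenario,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict]:
    """Generate (exposure tables by factor, outcome table, truth record).

    Tables use the default summary-table dialect (columns ``snp_id``,
    ``chrom``, ``pos``, ``effect_allele``, ``other_allele``, ``eaf``,
    ``beta``, ``se``, ``pval``). The truth record holds the latent exposure
    effects, pleiotropy vector and validity mask.
    """
    from scipy import stats

    rng = np.random.default_rng(scenario.seed)
    j, k = scenario.n_snp, scenario.k_factors

    snp_ids = [f"rs{1000 + i}" for i in range(j)]
    pairs = _SAFE_PAIRS + (_PALINDROMIC_PAIRS if scenario.allow_palindromic else [])
    alleles = [pairs[i] for i in rng.integers(0, len(pairs), size=j)]
    eaf = rng.uniform(0.05, 0.95, size=j)

    beta_x_true = _draw_truncated_normal(rng, scenario.beta_x_scale, (j, k))
    n_invalid = int(round(scenario.invalid_fraction * j))
    invalid = np.zeros(j, dtype=bool)
    if scenario.pleiotropy_mode != "none" and n_invalid > 0:
        invalid[rng.choice(j, size=n_invalid, replace=False)] = True
    alpha = np.zeros(j)
    if scenario.pleiotropy_mode == "balanced":
        alpha[invalid] = rng.normal(0.0, scenario.pleiotropy_sd, size=int(invalid.sum()))
    elif scenario.pleiotropy_mode == "directional":
        draw = rng.normal(
            scenario.pleiotropy_mean, scenario.pleiotropy_sd, size=int(invalid.sum())
        )
        # align with the exposure-increasing allele of the first factor
        alpha[invalid] = np.sign(beta_x_true[invalid, 0]) * draw
    gamma = beta_x_true @ np.asarray(scenario.theta_true) + alpha

    beta_x_obs = beta_x_true + rng.normal(0.0, scenario.se_x, size=(j, k))
    beta_y_obs = gamma + rng.normal(0.0, scenario.se_y, size=j)

    def table(beta: np.ndarray, se: float) -> pd.DataFrame:
        z = beta / se
        pval = 2.0 * stats.norm.sf(np.abs(z))
        pval = np.clip(pval, np.finfo(float).tiny, 1.0)
        return pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": ["1"] * j,
                "pos": np.arange(1, j + 1) * 10_000,
                "effect_allele": [a for a, _ in alleles],
                "other_allele": [b for _, b in alleles],
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": pval,
            }
        )

    exposures = {
        f"factor_{kk + 1}": table(beta_x_obs[:, kk], scenario.se_x) for kk in range(k)
    }
    outcome = table(beta_y_obs, scenario.se_y)
    truth = {
        "scenario": scenario,
        "snp_ids": snp_ids,
        "beta_x_true": beta_x_true,
        "alpha": alpha,
        "gamma": gamma,
        "invalid": invalid,
        "theta_true": np.asarray(scenario.theta_true),
    }
    return exposures, outcome, truth


def generated_instruments(
    scenario: SyntheticScenario, factor: int = 0
) -> list[HarmonisedInstrument]:
    """Convenience: generate a scenario and return ready-made instruments
    for one factor (already aligned, as both samples share the generator's
    allele coding)."""
    exposures, outcome, _ = generate(scenario)
    exp = list(exposures.values())[factor]
    return [
        HarmonisedInstrument(
            snp_id=str(e.snp_id),
            beta_x=float(e.beta),
            se_x=float(e.se),
            beta_y=float(o.beta),
            se_y=float(o.se),
            eaf_x=float(e.eaf),
            eaf_y=float(o.eaf),
            f_stat=(float(e.beta) / float(e.se)) ** 2,
        )
        for e, o in zip(exp.itertuples(), outcome.itertuples())
    ]
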