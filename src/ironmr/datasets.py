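"""Packaged instrument-level dataset: 12 SNPs x 4 iron biomarkers vs heart failure.

The table bundles the published instrument-level summary statistics for the
four systemic iron-status biomarkers (ferritin, iron, transferrin,
transferrin saturation) against heart failure in UK Biobank. Exposure and
outcome records share the same effect-allele coding, so the harmonised
instruments are a direct pairing.

Only the effect allele is published; the bundled ``other_allele`` column is
conventional fixture metadata for these well-known variants (see the file
header), supplied so the full harmonisation path can run. The published
per-SNP F statistics are carried as ``f_reported`` for reference; they are
not reproduced by (beta/se)² on the published inputs, so instrument-strength
filtering uses the recomputed values.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .mr_bma import BmaInput
from .summary_data import GwasRecord, HarmonisedInstrument

__all__ = [
    "BIOMARKERS",
    "table1_frame",
    "table1_records",
    "table1_fixture",
    "table1_bma_input",
]

#: exposure labels in table order
BIOMARKERS = ("ferritin", "iron", "transferrin", "ts")


def table1_frame() -> pd.DataFrame:
    """The raw fixture table as a DataFrame (one row per biomarker x SNP)."""
    with resources.files("ironmr.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    # p-values printed beyond float range underflow to 0 on parse
    df["p_exp"] = df["p_exp"].clip(lower=np.finfo(float).tiny)
    return df


def _record(row, which: str) -> GwasRecord:
    prefix = "exp" if which == "exposure" else "out"
    return GwasRecord(
        snp_id=row.snp_id,
        effect_allele=row.effect_allele,
        other_allele=row.other_allele,
        eaf=float(row.eaf),
        beta=float(getattr(row, f"beta_{prefix}")),
        se=float(getattr(row, f"se_{prefix}")),
        pval=float(getattr(row, f"p_{prefix}")),
        chrom=str(row.chrom),
        pos=int(row.pos),
    )


def table1_records() -> tuple[dict[str, list[GwasRecord]], list[GwasRecord]]:
    """(exposure records per biomarker, outcome records for the 12 SNPs)."""
    df = table1_frame()
    exposures: dict[str, list[GwasRecord]] = {}
    outcome: dict[str, GwasRecord] = {}
    for row in df.itertuples():
        exposures.setdefault(row.biomarker, []).append(_record(row, "exposure"))
        if row.snp_id not in outcome:
            outcome[row.snp_id] = _record(row, "outcome")
    return exposures, list(outcome.values())


def table1_fixture() -> dict[str, list[HarmonisedInstrument]]:
    """Harmonised instrument sets per biomarker, exactly as published.

    Exposure and outcome rows share their allele coding, so harmonisation is
    the identity pairing; instrument F statistics are recomputed as
    (beta/se)².
    """
    df = table1_frame()
    out: dict[str, list[HarmonisedInstrument]] = {}
    for row in df.itertuples():
        out.setdefault(row.biomarker, []).append(
            HarmonisedInstrument(
                snp_id=row.snp_id,
                beta_x=float(row.beta_exp),
                se_x=float(row.se_exp),
                beta_y=float(row.beta_out),
                se_y=float(row.se_out),
                eaf_x=float(row.eaf),
                eaf_y=float(row.eaf),
                f_stat=(float(row.beta_exp) / float(row.se_exp)) ** 2,
            )
        )
    return out


def table1_bma_input() -> BmaInput:
    """The 12-instrument x 4-biomarker matrix for model averaging.

    SNP x biomarker cells without a published association (the variant was
    not genome-wide significant for that biomarker) are set to zero: such a
    variant contributes no exposure signal for that factor.
    """
    df = table1_frame()
    snp_ids = list(dict.fromkeys(df.snp_id))
    j, k = len(snp_ids), len(BIOMARKERS)
    beta_x = np.zeros((j, k))
    se_x = np.zeros((j, k))
    beta_y = np.zeros(j)
    se_y = np.zeros(j)
    for row in df.itertuples():
        i = snp_ids.index(row.snp_id)
        kk = BIOMARKERS.index(row.biomarker)
        beta_x[i, kk] = row.beta_exp
        se_x[i, kk] = row.se_exp
        beta_y[i] = row.beta_out
        se_y[i] = row.se_out
    return BmaInput(
        beta_x=beta_x,
        beta_y=beta_y,
        se_y=se_y,
        se_x=se_x,
        factor_names=BIOMARKERS,
        snp_ids=tuple(snp_ids),
    )
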