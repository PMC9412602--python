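"""End-to-end study orchestration and the ``ironmr`` command line.

:func:`run_study` reproduces the full analysis flow on either the packaged
instrument fixture or user-supplied summary tables: instrument selection
(significance, LD pruning, palindrome removal, weak-instrument filter) →
harmonisation → univariable MR (IVW, MR-Egger, weighted median; both the
shared-instrument analysis restricted to SNPs present in every exposure set
and the full per-exposure sets) → sensitivity suite (Cochran's Q,
leave-one-out, funnel table) → Bayesian model averaging with iterative
instrument exclusion → optional multivariable MR. Every stage writes TSVs
plus a JSON report; all stochastic stages are driven by the configured
seed, so a re-run with the same config reproduces every number bit for bit.

No multiple-testing adjustment is applied across exposures: reported
p-values are nominal, and readers comparing four biomarkers should keep
that in mind.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import table1_bma_input, table1_fixture
from .mr_bma import MRBMA
from .mr_core import IVW, MREgger, WeightedMedian
from .mvmr import MVMR
from .sensitivity import cochran_q, funnel_data, leave_one_out
from .summary_data import (
    HarmonisedInstrument,
    LdMatrix,
    filter_weak,
    harmonise,
    ld_prune,
    read_summary_table,
    select_instruments,
)
from .synthetic_data import SyntheticScenario, generate

__all__ = ["StudyConfig", "run_study", "run_binary_exposure_mr", "cli"]

BINARY_EXPOSURE_CAVEAT = (
    "Exposure is dichotomous (disease status): causal estimates are per unit "
    "of log-odds liability and competing-risk bias cannot be excluded."
)


@dataclass
class StudyConfig:
    """Thresholds, seeds and IO paths for one study run."""

    fixture: str | None = "table1"          # packaged fixture selector, or None
    exposure_paths: dict[str, str] = field(default_factory=dict)
    outcome_path: str | None = None
    ld_matrix_path: str | None = None
    out_dir: str = "ironmr_out"
    p_select: float = 5e-8
    ld_r2: float = 0.01
    proxy_r2: float = 0.8
    f_min: float = 10.0
    alpha: float = 0.05
    bma_prior_prob: float = 0.1
    bma_sigma: float = 0.5
    q_max: float = 10.0
    pp_threshold: float = 0.02
    n_boot: int = 5000
    seed: int = 2022
    run_mvmr: bool = True
    binary_exposure: bool = False

    def __post_init__(self) -> None:
        checks = {
            "p_select": 0 < self.p_select <= 1,
            "ld_r2": 0 < self.ld_r2 <= 1,
            "proxy_r2": 0 <= self.proxy_r2 < 1,
            "f_min": self.f_min >= 0,
            "alpha": 0 < self.alpha < 1,
            "bma_prior_prob": 0 < self.bma_prior_prob < 1,
            "bma_sigma": self.bma_sigma > 0,
            "pp_threshold": 0 <= self.pp_threshold <= 1,
            "n_boot": self.n_boot >= 1,
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"config values out of range: {bad}")
        if self.fixture is None and not self.exposure_paths:
            raise ValueError("either a fixture or exposure tables must be given")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class StudyReport:
    """All result tables of one run plus the config echo."""

    config: StudyConfig
    mr_estimates: pd.DataFrame
    heterogeneity: pd.DataFrame
    leave_one_out: pd.DataFrame
    funnel: pd.DataFrame
    selection_log: pd.DataFrame
    bma_panels: pd.DataFrame
    bma_diagnostics: pd.DataFrame
    bma_trail: list[tuple[str, str, float]]
    mvmr_table: pd.DataFrame | None
    caveats: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        out = {
            "software": {"ironmr": __version__, "python": platform.python_version()},
            "config": asdict(self.config),
            "caveats": self.caveats,
            "mr_estimates": self.mr_estimates.to_dict(orient="records"),
            "heterogeneity": self.heterogeneity.to_dict(orient="records"),
            "leave_one_out": self.leave_one_out.to_dict(orient="records"),
            "funnel": self.funnel.to_dict(orient="records"),
            "selection_log": self.selection_log.to_dict(orient="records"),
            "bma_panels": self.bma_panels.to_dict(orient="records"),
            "bma_diagnostics": self.bma_diagnostics.to_dict(orient="records"),
            "bma_trail": [list(t) for t in self.bma_trail],
        }
        if self.mvmr_table is not None:
            out["mvmr"] = self.mvmr_table.to_dict(orient="records")
        return out

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "mr_estimates.tsv": self.mr_estimates,
            "heterogeneity.tsv": self.heterogeneity,
            "leave_one_out.tsv": self.leave_one_out,
            "funnel.tsv": self.funnel,
            "selection_log.tsv": self.selection_log,
            "bma_panels.tsv": self.bma_panels,
            "bma_diagnostics.tsv": self.bma_diagnostics,
        }
        if self.mvmr_table is not None:
            tables["mvmr.tsv"] = self.mvmr_table
        written = []
        try:
            for name, df in tables.items():
                df.to_csv(out / name, sep="\t", index=False)
                written.append(name)
            with open(out / "report.json", "w") as fh:
                json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            written.append("report.json")
        finally:
            with open(out / "MANIFEST", "w") as fh:
                complete = len(written) == len(tables) + 1
                fh.write(f"complete: {str(complete).lower()}\n")
                for name in written:
                    fh.write(name + "\n")


def _load_instruments(config: StudyConfig) -> tuple[dict[str, list[HarmonisedInstrument]], pd.DataFrame]:
    """Instrument sets per exposure plus the combined selection log."""
    logs: list[dict] = []
    if config.fixture is not None:
        if config.fixture != "table1":
            raise ValueError(f"unknown fixture '{config.fixture}'")
        sets = table1_fixture()
        # fixture is pre-harmonised; still apply the weak-instrument guard
        out: dict[str, list[HarmonisedInstrument]] = {}
        for name, instruments in sets.items():
            kept = filter_weak(instruments, f_min=config.f_min, exposure_name=name)
            out[name] = kept.instruments
            logs.extend(
                {"exposure": name, "snp_id": s, "rule": r, "detail": d}
                for s, r, d in kept.selection_log
            )
        return out, pd.DataFrame(logs, columns=["exposure", "snp_id", "rule", "detail"])

    if config.outcome_path is None:
        raise ValueError("outcome_path is required when exposure tables are supplied")
    outcome = read_summary_table(config.outcome_path)
    outcome_by_id = {r.snp_id: r for r in outcome}
    ld = (
        LdMatrix.from_table(config.ld_matrix_path)
        if config.ld_matrix_path
        else LdMatrix({})
    )
    result: dict[str, list[HarmonisedInstrument]] = {}
    for name, path in config.exposure_paths.items():
        records = read_summary_table(path)
        selected = select_instruments(records, config.p_select)
        for rec in records:
            if rec not in selected:
                logs.append(
                    {"exposure": name, "snp_id": rec.snp_id, "rule": "p_threshold",
                     "detail": f"p={rec.pval:.3g} >= {config.p_select}"}
                )
        prune_log: list[tuple[str, str, str]] = []
        selected = ld_prune(selected, ld, config.ld_r2, log=prune_log)
        logs.extend(
            {"exposure": name, "snp_id": s, "rule": r, "detail": d} for s, r, d in prune_log
        )
        harmonised: list[HarmonisedInstrument] = []
        hlog: list[tuple[str, str, str]] = []
        for rec in selected:
            target = outcome_by_id.get(rec.snp_id)
            proxy_of = ""
            if target is None:
                from .summary_data import find_proxy

                proxy = find_proxy(rec.snp_id, outcome, ld, config.proxy_r2)
                if proxy is None:
                    hlog.append((rec.snp_id, "missing_in_outcome", "no proxy found"))
                    continue
                target, proxy_of = proxy, rec.snp_id
            inst = harmonise(rec, target, drop_palindromic=True, proxy_of=proxy_of, log=hlog)
            if inst is not None:
                harmonised.append(inst)
        logs.extend(
            {"exposure": name, "snp_id": s, "rule": r, "detail": d} for s, r, d in hlog
        )
        kept = filter_weak(harmonised, f_min=config.f_min, exposure_name=name)
        logs.extend(
            {"exposure": name, "snp_id": s, "rule": r, "detail": d}
            for s, r, d in kept.selection_log
        )
        result[name] = kept.instruments
    return result, pd.DataFrame(logs, columns=["exposure", "snp_id", "rule", "detail"])


def _univariable_suite(
    name: str, instruments: list[HarmonisedInstrument], config: StudyConfig, analysis: str
) -> pd.DataFrame:
    frames = [IVW(instruments, model="fixed", exposure=name).fit().summary()]
    if len(instruments) >= 2:
        frames.append(IVW(instruments, model="random", exposure=name).fit().summary())
    if len(instruments) >= 3:
        frames.append(MREgger(instruments, exposure=name).fit().as_mr_results().summary())
        frames.append(
            WeightedMedian(
                instruments, n_boot=config.n_boot, seed=config.seed, exposure=name
            )
            .fit()
            .summary()
        )
    return pd.concat(frames, ignore_index=True).assign(analysis=analysis)


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full workflow and return (and optionally write) the report."""
    stage = "instrument selection"
    try:
        sets, selection_log = _load_instruments(config)

        stage = "univariable MR"
        mr_frames = []
        shared = None
        ids_per_set = [set(i.snp_id for i in s) for s in sets.values()]
        if len(ids_per_set) > 1:
            shared = set.intersection(*ids_per_set)
        for name, instruments in sets.items():
            mr_frames.append(_univariable_suite(name, instruments, config, "full_set"))
            if shared and len(shared) >= 2:
                subset = [i for i in instruments if i.snp_id in shared]
                mr_frames.append(
                    _univariable_suite(name, subset, config, "shared_snps")
                )
        mr_estimates = pd.concat(mr_frames, ignore_index=True)

        stage = "sensitivity"
        het, loo, funnel = [], [], []
        egger_rows = []
        for name, instruments in sets.items():
            if len(instruments) >= 2:
                h = cochran_q(instruments)
                het.append({"exposure": name, "q": h.q, "df": h.df, "pval": h.pval})
                for row in leave_one_out(instruments).rows:
                    loo.append(
                        {"exposure": name, "excluded_snp": row[0], "theta": row[1],
                         "se": row[2], "pval": row[3]}
                    )
            if len(instruments) >= 3:
                e = MREgger(instruments, exposure=name).fit()
                egger_rows.append(
                    {"exposure": name, "intercept": e.intercept,
                     "se_intercept": e.se_intercept, "p_intercept": e.p_intercept}
                )
            for pt in funnel_data(instruments):
                funnel.append(
                    {"exposure": name, "snp_id": pt.snp_id, "theta": pt.theta,
                     "precision": pt.precision}
                )
        heterogeneity = pd.DataFrame(het)
        if egger_rows:
            heterogeneity = heterogeneity.merge(
                pd.DataFrame(egger_rows), on="exposure", how="left"
            )

        stage = "MR-BMA"
        bma_panels = pd.DataFrame()
        bma_diag = pd.DataFrame()
        trail: list[tuple[str, str, float]] = []
        if config.fixture is not None or len(sets) > 1:
            bma_input = (
                table1_bma_input() if config.fixture is not None else _bma_from_sets(sets)
            )
            model = MRBMA(
                bma_input, prior_prob=config.bma_prior_prob, sigma=config.bma_sigma
            )
            final, trail, stages = model.fit_with_exclusion(q_max=config.q_max)
            panels, diags = [], []
            for idx, res in enumerate(stages):
                res_perm = res
                panel = res_perm.summary(pp_threshold=config.pp_threshold).assign(
                    stage=idx, n_snp=res.input.n_snp
                )
                panels.append(panel)
                diags.append(
                    res.diagnostics_frame().assign(
                        stage=idx,
                        excluded=lambda df: df.snp_id.isin(
                            {t[0] for t in trail[idx : idx + 1]}
                        ),
                    )
                )
            bma_panels = pd.concat(panels, ignore_index=True)
            bma_diag = pd.concat(diags, ignore_index=True)

        stage = "MVMR"
        mvmr_table = None
        if config.run_mvmr and (config.fixture is not None or len(sets) > 1):
            bma_input = (
                table1_bma_input() if config.fixture is not None else _bma_from_sets(sets)
            )
            mvmr_table = MVMR(bma_input).fit().summary()

        caveats = [BINARY_EXPOSURE_CAVEAT] if config.binary_exposure else []
        report = StudyReport(
            config=config,
            mr_estimates=mr_estimates,
            heterogeneity=heterogeneity,
            leave_one_out=pd.DataFrame(loo),
            funnel=pd.DataFrame(funnel),
            selection_log=selection_log,
            bma_panels=bma_panels,
            bma_diagnostics=bma_diag,
            bma_trail=trail,
            mvmr_table=mvmr_table,
            caveats=caveats,
        )
    except Exception as exc:
        raise RuntimeError(f"study failed at stage '{stage}': {exc}") from exc
    if config.out_dir:
        report.write(config.out_dir)
    return report


def _bma_from_sets(sets: dict[str, list[HarmonisedInstrument]]):
    from .mr_bma import BmaInput

    snp_ids: list[str] = []
    for instruments in sets.values():
        for inst in instruments:
            if inst.snp_id not in snp_ids:
                snp_ids.append(inst.snp_id)
    names = tuple(sets)
    j, k = len(snp_ids), len(names)
    beta_x = np.zeros((j, k))
    beta_y = np.full(j, np.nan)
    se_y = np.full(j, np.nan)
    for kk, (name, instruments) in enumerate(sets.items()):
        for inst in instruments:
            i = snp_ids.index(inst.snp_id)
            beta_x[i, kk] = inst.beta_x
            beta_y[i] = inst.beta_y
            se_y[i] = inst.se_y
    if np.isnan(beta_y).any():
        raise ValueError("outcome effects missing for some instruments")
    return BmaInput(
        beta_x=beta_x, beta_y=beta_y, se_y=se_y, factor_names=names,
        snp_ids=tuple(snp_ids),
    )


def run_binary_exposure_mr(config: StudyConfig) -> StudyReport:
    """Univariable pipeline for a dichotomous (disease) exposure.

    Identical flow with MR-BMA/MVMR disabled and a caveat banner recorded in
    the report: with a binary exposure the estimates are per unit log-odds
    liability and competing risks cannot be excluded.
    """
    cfg_dict = asdict(config)
    cfg_dict.update(binary_exposure=True, run_mvmr=False)
    cfg = StudyConfig(**cfg_dict)
    if cfg.fixture is None:
        for name, path in cfg.exposure_paths.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"exposure table for '{name}' not found: {path}")
        if cfg.outcome_path is None or not Path(cfg.outcome_path).exists():
            raise FileNotFoundError(f"outcome table not found: {cfg.outcome_path}")
    return run_study(cfg)


# ---------------------------------------------------------------------------
# command-line interface


@click.group()
@click.version_option(__version__)
def cli() -> None:
    """Two-sample Mendelian randomisation toolkit."""


@cli.command("run")
@click.option("--config", "config_path", type=click.Path(exists=True), required=True,
              help="YAML study configuration.")
def cli_run(config_path: str) -> None:
    """Run the full study described by a YAML config."""
    config = StudyConfig.from_yaml(config_path)
    report = run_study(config)
    click.echo(report.mr_estimates.to_string(index=False))
    click.echo(f"outputs written to {config.out_dir}")


@cli.command("fixture")
@click.option("--name", default="table1", show_default=True)
@click.option("--out", type=click.Path(), default=None, help="Write the table as TSV.")
def cli_fixture(name: str, out: str | None) -> None:
    """Print (or export) a packaged instrument table."""
    if name != "table1":
        raise click.ClickException(f"unknown fixture '{name}'")
    from .datasets import table1_frame

    df = table1_frame()
    if out:
        df.to_csv(out, sep="\t", index=False)
        click.echo(f"wrote {out}")
    else:
        click.echo(df.to_string(index=False))


@cli.command("simulate")
@click.option("--scenario", "scenario_path", type=click.Path(exists=True), required=True,
              help="YAML file of SyntheticScenario fields.")
@click.option("--out-dir", type=click.Path(), required=True)
def cli_simulate(scenario_path: str, out_dir: str) -> None:
    """Generate synthetic summary tables with known ground truth."""
    with open(scenario_path) as fh:
        fields = yaml.safe_load(fh) or {}
    if "theta_true" in fields:
        fields["theta_true"] = tuple(fields["theta_true"])
    scenario = SyntheticScenario(**fields)
    exposures, outcome, truth = generate(scenario)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in exposures.items():
        df.to_csv(out / f"exposure_{name}.tsv", sep="\t", index=False)
    outcome.to_csv(out / "outcome.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "snp_ids": truth["snp_ids"],
                "theta_true": truth["theta_true"].tolist(),
                "beta_x_true": truth["beta_x_true"].tolist(),
                "alpha": truth["alpha"].tolist(),
                "invalid": truth["invalid"].tolist(),
            },
            fh,
            indent=2,
        )
    click.echo(f"wrote {len(exposures)} exposure table(s) + outcome + truth to {out}")


@cli.command("bma")
@click.option("--prior-prob", default=0.1, show_default=True)
@click.option("--sigma", default=0.5, show_default=True)
@click.option("--q-max", default=10.0, show_default=True)
def cli_bma(prior_prob: float, sigma: float, q_max: float) -> None:
    """Model-averaged multivariable MR on the packaged fixture."""
    model = MRBMA(table1_bma_input(), prior_prob=prior_prob, sigma=sigma)
    final, trail, stages = model.fit_with_exclusion(q_max=q_max)
    for idx, res in enumerate(stages):
        click.echo(f"--- stage {idx}: {res.input.n_snp} SNPs ---")
        click.echo(res.summary().to_string(index=False))
    if trail:
        click.echo("exclusions: " + ", ".join(f"{s} ({r}={v:.3g})" for s, r, v in trail))


@cli.command("mvmr")
def cli_mvmr() -> None:
    """Multivariable IVW on the packaged fixture."""
    res = MVMR(table1_bma_input()).fit()
    click.echo(res.summary().to_string(index=False))
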