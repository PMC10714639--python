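"""Run configuration and bit-stable tabular outputs.

Thin orchestration over the library: each entry point loads (or defaults)
parameters and the life table, runs the requested analysis, and writes CSVs
with fixed float formatting so that identical configurations produce
byte-identical files.  A metadata JSON records the seed, accounting
conventions and package version alongside every run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import SimulationSettings, run_all_strategies
from .disease_model import PERSPECTIVES, STRATEGIES
from .economics import incremental_vs_comparator
from .life_table import LifeTable, gompertz_life_table, load_life_table
from .params import ParameterSet, default_parameters, load_parameters
from .sensitivity import DEFAULT_WTP_GRID, ceac, psa_run, tornado
from .synthetic import (
    state_cost_means,
    state_utility_means,
    synth_claims_episodes,
    synth_eq5d_survey,
)

__all__ = ["RunConfig", "cmd_base_case", "cmd_dsa", "cmd_psa", "cmd_synth"]

_FLOAT_FMT = "%.6f"


@dataclass
class RunConfig:
    """Everything a reporting run needs; flags and config files map onto this."""

    out_dir: str | Path = "pdrcea-out"
    params_path: str | Path | None = None
    life_table_path: str | Path | None = None
    strategies: list[str] = field(default_factory=lambda: list(STRATEGIES))
    perspectives: list[str] = field(default_factory=lambda: list(PERSPECTIVES))
    comparator: str = "prp-only"
    discount_rate: float | None = None
    psa_n: int = 10_000
    seed: int = 2020
    wtp_max: float = 100_000.0
    wtp_step: float = 1_000.0
    plot: bool = False

    def validate(self) -> None:
        if self.psa_n < 1:
            raise ValueError("PSA sample count must be >= 1")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")
        unknown = set(self.perspectives) - set(PERSPECTIVES)
        if unknown:
            raise ValueError(f"unknown perspectives: {sorted(unknown)}")
        if self.comparator not in self.strategies:
            raise ValueError(f"comparator {self.comparator!r} not among strategies")

    def load_inputs(self) -> tuple[ParameterSet, LifeTable, SimulationSettings]:
        params = (load_parameters(self.params_path, fill_defaults=True)
                  if self.params_path else default_parameters())
        lt = (load_life_table(self.life_table_path)
              if self.life_table_path else gompertz_life_table())
        settings = SimulationSettings(discount_rate=self.discount_rate)
        return params, lt, settings

    def wtp_grid(self) -> np.ndarray:
        return np.arange(0.0, self.wtp_max + self.wtp_step / 2, self.wtp_step)


def _outdir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_metadata(config: RunConfig, out: Path, extra: dict | None = None) -> Path:
    meta = {
        "package_version": __version__,
        "seed": config.seed,
        "comparator": config.comparator,
        "conventions": {
            "cycle_length_years": 1,
            "start_age": 50,
            "end_age": 100,
            "discount_exponent_starts_at": 0,
            "half_cycle_correction": False,
            "currency": "2020 USD",
        },
    }
    meta.update(extra or {})
    path = out / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def cmd_base_case(config: RunConfig) -> list[Path]:
    """Write per-perspective incremental tables (CSV + readable text)."""
    config.validate()
    params, lt, settings = config.load_inputs()
    results = run_all_strategies(params, lt, settings, config.strategies)
    out = _outdir(config)
    written = []
    lines = []
    for persp in config.perspectives:
        rows = incremental_vs_comparator(results, config.comparator, persp)
        df = pd.DataFrame(
            {
                "strategy": [r.strategy for r in rows],
                "cost": [r.cost for r in rows],
                "incremental_cost": [
                    "" if r.is_comparator else f"{r.delta_cost:.6f}" for r in rows
                ],
                "qaly": [r.qaly for r in rows],
                "incremental_qaly": [
                    "" if r.is_comparator else f"{r.delta_qaly:.6f}" for r in rows
                ],
                "icer": [
                    "" if r.is_comparator
                    else (r.label if r.icer is None else f"{r.icer:.2f}")
                    for r in rows
                ],
            }
        )
        path = out / f"incremental_{persp}.csv"
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)
        lines.append(f"== {persp} perspective ==")
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:,.2f}"))
        lines.append("")
    txt = out / "base_case.txt"
    txt.write_text("\n".join(lines))
    written.append(txt)
    written.append(_write_metadata(config, out, {"analysis": "base-case"}))
    return written


def cmd_dsa(config: RunConfig, strategy: str | None = None,
            perspective: str = "healthcare") -> list[Path]:
    """Write the one-way sensitivity (tornado) table, widest swing first."""
    config.validate()
    params, lt, settings = config.load_inputs()
    strategy = strategy or "antivegf-only"
    entries = tornado((strategy, config.comparator), perspective, params, lt,
                      settings)
    df = pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "swing": [e.swing for e in entries],
        }
    )
    out = _outdir(config)
    path = out / "tornado.csv"
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    written = [path, _write_metadata(config, out, {
        "analysis": "dsa", "strategy": strategy, "perspective": perspective,
        "base_icer": entries[0].base_icer if entries else None,
    })]
    if config.plot:
        written.append(_plot_tornado(df, out / "tornado.png"))
    return written


def cmd_psa(config: RunConfig) -> list[Path]:
    """Write the PSA draw table and a CEAC CSV per perspective."""
    config.validate()
    params, lt, settings = config.load_inputs()
    draws = psa_run(config.psa_n, config.seed, params, lt, settings,
                    config.strategies)
    out = _outdir(config)
    written = []
    path = out / "psa_draws.csv"
    draws.to_csv(path, index=False, float_format=_FLOAT_FMT)
    written.append(path)
    for persp in config.perspectives:
        curve = ceac(draws, config.wtp_grid(), persp)
        cpath = out / f"ceac_{persp}.csv"
        curve.prob.to_csv(cpath, float_format=_FLOAT_FMT)
        written.append(cpath)
        if config.plot:
            written.append(_plot_ceac(curve, out / f"ceac_{persp}.png"))
    written.append(_write_metadata(config, out, {
        "analysis": "psa", "psa_n": config.psa_n,
    }))
    return written


def cmd_synth(config: RunConfig, n_patient_years: int = 1000,
              survey_n: int = 300) -> list[Path]:
    """Write synthetic claims episodes, survey responses and a life table."""
    config.validate()
    params, lt, _ = config.load_inputs()
    out = _outdir(config)
    episodes = synth_claims_episodes(
        state_cost_means(params), n_patient_years, seed=config.seed
    )
    survey = synth_eq5d_survey(
        state_utility_means(params), n=survey_n, seed=config.seed + 1
    )
    paths = [out / "episodes.csv", out / "survey.csv", out / "life_table.csv"]
    episodes.to_csv(paths[0], index=False, float_format=_FLOAT_FMT)
    survey.to_csv(paths[1], index=False, float_format=_FLOAT_FMT)
    lt.to_csv(paths[2])
    paths.append(_write_metadata(config, out, {"analysis": "synth"}))
    return paths


def _plot_tornado(df: pd.DataFrame, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = df.head(15).iloc[::-1]
    base = (top["icer_low"] + top["icer_high"]).iloc[-1] / 2
    fig, ax = plt.subplots(figsize=(8, 6))
    lo = np.minimum(top["icer_low"], top["icer_high"])
    hi = np.maximum(top["icer_low"], top["icer_high"])
    ax.barh(top["parameter"], hi - lo, left=lo, color="#4477aa")
    ax.axvline(base, color="k", lw=0.8)
    ax.set_xlabel("ICER (USD/QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _plot_ceac(curve, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for col in curve.prob.columns:
        ax.plot(curve.wtp, curve.prob[col], label=col)
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_title(f"{curve.perspective} perspective")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
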