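"""Deterministic (tornado) and probabilistic sensitivity analysis with CEACs.

One-way analysis re-evaluates a pairwise ICER with a single parameter pushed
to each of its deterministic bounds (published +/-20% ranges, or the 95% CI
for relative risks), all else at base.  The probabilistic analysis draws all
parameters jointly from their constructed distributions, reruns the cohort
model per draw and strategy, and summarises the draws as cost-effectiveness
acceptability curves: at each willingness-to-pay value, the fraction of draws
in which each strategy attains the maximal net monetary benefit (ties split
equally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SimulationSettings, run_cohort
from .disease_model import PERSPECTIVES, STRATEGIES
from .life_table import LifeTable
from .params import ParameterError, ParameterSet, sample_parameter_set

__all__ = [
    "TornadoEntry",
    "CEACCurve",
    "DEFAULT_WTP_GRID",
    "one_way",
    "tornado",
    "psa_run",
    "ceac",
    "threshold_wtp",
]

#: default willingness-to-pay grid: 0-100,000 USD/QALY in 1,000-dollar steps
DEFAULT_WTP_GRID = np.arange(0, 100_001, 1_000, dtype=float)


@dataclass
class TornadoEntry:
    """One parameter's one-way ICER excursion for a strategy pair."""

    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float
    base_icer: float

    @property
    def swing(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _pair_icer(strategy, comparator, perspective, params, lt, settings):
    _, rs = run_cohort(strategy, params, lt, settings)
    _, rc = run_cohort(comparator, params, lt, settings)
    dc = rs.cost[perspective] - rc.cost[perspective]
    dq = rs.qaly - rc.qaly
    if dq == 0.0:
        return math.copysign(math.inf, dc) if dc else 0.0
    return dc / dq


def _censored(params: ParameterSet, name: str, value: float) -> float:
    # utilities may only reach 1 (published censoring rule)
    if params.table[name].units == "utility":
        return min(1.0, value)
    return value


def one_way(
    name: str,
    strategy_pair: tuple[str, str],
    perspective: str,
    params: ParameterSet,
    lt: LifeTable,
    settings: SimulationSettings | None = None,
) -> TornadoEntry:
    """ICER of ``strategy_pair = (strategy, comparator)`` with one parameter
    at each deterministic bound, everything else at base."""
    if name not in params.table:
        raise ParameterError(f"unknown parameter {name!r}")
    bounds = params.table[name].dsa_bounds()
    if bounds is None:
        raise ParameterError(f"parameter {name!r} has no sensitivity range")
    lo, hi = bounds
    s, c = strategy_pair
    base_icer = _pair_icer(s, c, perspective, params, lt, settings)
    icer_lo = _pair_icer(
        s, c, perspective,
        params.with_values(provenance="dsa-low", **{name: _censored(params, name, lo)}),
        lt, settings,
    )
    icer_hi = _pair_icer(
        s, c, perspective,
        params.with_values(provenance="dsa-high", **{name: _censored(params, name, hi)}),
        lt, settings,
    )
    return TornadoEntry(name, lo, hi, icer_lo, icer_hi, base_icer)


def tornado(
    strategy_pair: tuple[str, str],
    perspective: str,
    params: ParameterSet,
    lt: LifeTable,
    settings: SimulationSettings | None = None,
) -> list[TornadoEntry]:
    """One-way entries for every ranged parameter, widest swing first.

    Ordering is deterministic (swing descending, name as tie-break) and
    invariant to the table's iteration order.
    """
    entries = [
        one_way(name, strategy_pair, perspective, params, lt, settings)
        for name, p in params.table.items()
        if p.dsa_bounds() is not None
    ]
    return sorted(entries, key=lambda e: (-e.swing, e.parameter))


def psa_run(
    n: int,
    seed: int,
    params: ParameterSet,
    lt: LifeTable,
    settings: SimulationSettings | None = None,
    strategies: list[str] | None = None,
) -> pd.DataFrame:
    """Probabilistic sensitivity analysis: ``n`` joint parameter draws, a
    full cohort run per draw and strategy.

    Returns a tidy table with one row per (draw, strategy): discounted QALYs
    and discounted lifetime cost under each perspective.  Bitwise
    reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = strategies or list(STRATEGIES)
    rng = np.random.default_rng(seed)
    rows = []
    for draw in range(n):
        ps = sample_parameter_set(params, rng)
        for name in names:
            _, res = run_cohort(name, ps, lt, settings)
            row = {"draw": draw, "strategy": name, "qaly": res.qaly}
            for p in PERSPECTIVES:
                row[f"cost_{p}"] = res.cost[p]
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CEACCurve:
    """Probability each strategy is optimal (maximal NMB) at each WTP."""

    wtp: np.ndarray
    prob: pd.DataFrame  # index: wtp, columns: strategy names
    perspective: str

    def strategies(self) -> list[str]:
        return list(self.prob.columns)


def ceac(
    psa_output: pd.DataFrame,
    wtp_grid: np.ndarray | None = None,
    perspective: str = "healthcare",
) -> CEACCurve:
    """Cost-effectiveness acceptability curves from a PSA draw table.

    For each WTP on the grid, each strategy's probability of attaining the
    maximal net monetary benefit across draws; exact ties split equally, so
    probabilities sum to 1 at every grid point.
    """
    if psa_output.empty:
        raise ValueError("psa_output is empty")
    wtp = np.asarray(DEFAULT_WTP_GRID if wtp_grid is None else wtp_grid, float)
    q = psa_output.pivot(index="draw", columns="strategy", values="qaly")
    c = psa_output.pivot(index="draw", columns="strategy",
                         values=f"cost_{perspective}")
    strategies = list(q.columns)
    qv, cv = q.to_numpy(), c.to_numpy()
    probs = np.zeros((len(wtp), len(strategies)))
    for i, w in enumerate(wtp):
        nmb = w * qv - cv
        best = nmb.max(axis=1, keepdims=True)
        wins = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        probs[i] = (wins / wins.sum(axis=1, keepdims=True)).mean(axis=0)
    return CEACCurve(
        wtp=wtp,
        prob=pd.DataFrame(probs, index=pd.Index(wtp, name="wtp"),
                          columns=strategies),
        perspective=perspective,
    )


def threshold_wtp(curve: CEACCurve, a: str, b: str) -> float | None:
    """Smallest WTP at which strategy ``b`` first overtakes ``a`` on the
    acceptability curve, linearly interpolated between grid points; None if
    ``b`` never exceeds ``a``."""
    for s in (a, b):
        if s not in curve.prob.columns:
            raise ValueError(f"strategy {s!r} not in curve")
    diff = (curve.prob[b] - curve.prob[a]).to_numpy()
    above = np.nonzero(diff > 0)[0]
    if len(above) == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(curve.wtp[0])
    w0, w1 = curve.wtp[i - 1], curve.wtp[i]
    d0, d1 = diff[i - 1], diff[i]
    if d1 == d0:
        return float(w1)
    return float(w0 + (0.0 - d0) * (w1 - w0) / (d1 - d0))
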