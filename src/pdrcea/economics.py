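"""Incremental cost-effectiveness, dominance and net monetary benefit.

The primary comparison reports every strategy against a designated comparator
(the insurance-covered PRP-only policy), mirroring standard practice when one
option is the reimbursed standard of care.  A sequential efficiency frontier
with strict and extended dominance pruning is also provided.  ICERs are kept
unrounded internally; any display rounding belongs to the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import StrategyResult

__all__ = [
    "IncrementalRow",
    "FrontierResult",
    "incremental_vs_comparator",
    "efficiency_frontier",
    "nmb",
]

_EPS = 1e-12

COST_SAVING = "cost-saving"
DOMINATED = "dominated"
TRADEOFF_SW = "less costly, less effective"


@dataclass
class IncrementalRow:
    """One strategy's comparison against the comparator.

    ``icer`` is reported only when both increments are positive; otherwise a
    dominance ``label`` is set ("cost-saving" when the strategy saves money
    without losing effectiveness, "dominated" when it costs at least as much
    for no gain).
    """

    strategy: str
    comparator: str
    cost: float
    qaly: float
    delta_cost: float
    delta_qaly: float
    icer: float | None = None
    label: str | None = None

    @property
    def is_comparator(self) -> bool:
        return self.strategy == self.comparator


def _classify(dc: float, dq: float) -> tuple[float | None, str | None]:
    if abs(dc) < _EPS and abs(dq) < _EPS:
        return None, None
    if dc > _EPS and dq > _EPS:
        return dc / dq, None
    if dc < -_EPS and dq < -_EPS:
        return None, TRADEOFF_SW
    if dc <= _EPS and dq >= -_EPS:  # saves cost, at least as effective
        return None, COST_SAVING
    return None, DOMINATED  # costs >= with no gain (or a loss)


def incremental_vs_comparator(
    results: list[StrategyResult], comparator: str, perspective: str
) -> list[IncrementalRow]:
    """Incremental cost/QALY of each strategy against ``comparator``.

    The comparator itself appears as a zero row (no ICER, no label); input
    order is preserved.
    """
    by_name = {r.strategy: r for r in results}
    if comparator not in by_name:
        raise ValueError(f"comparator {comparator!r} not among results")
    ref = by_name[comparator]
    rows = []
    for r in results:
        dc = r.cost[perspective] - ref.cost[perspective]
        dq = r.qaly - ref.qaly
        icer, label = _classify(dc, dq)
        rows.append(
            IncrementalRow(
                strategy=r.strategy,
                comparator=comparator,
                cost=r.cost[perspective],
                qaly=r.qaly,
                delta_cost=dc,
                delta_qaly=dq,
                icer=icer,
                label=label,
            )
        )
    return rows


@dataclass
class FrontierResult:
    """Cost-ordered efficiency frontier plus labels for removed strategies."""

    frontier: list[StrategyResult]
    dominated: dict[str, str]  # strategy -> "strictly dominated" | "extendedly dominated"

    @property
    def frontier_names(self) -> list[str]:
        return [r.strategy for r in self.frontier]


def efficiency_frontier(
    results: list[StrategyResult], perspective: str
) -> FrontierResult:
    """Strict and extended dominance pruning.

    A strategy is strictly dominated when another costs no more and yields at
    least as many QALYs (one inequality strict).  Extended dominance then
    removes interior points whose incremental ICER exceeds that of the next
    frontier step (strictly — collinear points are kept).  Output is
    invariant to input ordering.
    """
    if len(results) < 2:
        return FrontierResult(list(results), {})
    dominated: dict[str, str] = {}
    pts = sorted(results, key=lambda r: (r.cost[perspective], -r.qaly, r.strategy))

    survivors = []
    for r in pts:
        strict = any(
            (o.cost[perspective] <= r.cost[perspective] + _EPS
             and o.qaly >= r.qaly - _EPS
             and (o.cost[perspective] < r.cost[perspective] - _EPS
                  or o.qaly > r.qaly + _EPS))
            for o in pts if o is not r
        )
        if strict:
            dominated[r.strategy] = "strictly dominated"
        else:
            survivors.append(r)

    changed = True
    while changed and len(survivors) > 2:
        changed = False
        for i in range(1, len(survivors) - 1):
            a, b, c = survivors[i - 1], survivors[i], survivors[i + 1]
            icer_ab = _seg_icer(a, b, perspective)
            icer_bc = _seg_icer(b, c, perspective)
            if icer_ab is not None and icer_bc is not None and icer_ab > icer_bc + _EPS:
                dominated[b.strategy] = "extendedly dominated"
                survivors.pop(i)
                changed = True
                break
    return FrontierResult(survivors, dominated)


def _seg_icer(a: StrategyResult, b: StrategyResult, perspective: str) -> float | None:
    dq = b.qaly - a.qaly
    dc = b.cost[perspective] - a.cost[perspective]
    if abs(dq) < _EPS:
        return None
    return dc / dq


def nmb(result: StrategyResult, wtp: float, perspective: str) -> float:
    """Net monetary benefit at a willingness-to-pay threshold:
    ``wtp * QALY - cost``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.qaly - result.cost[perspective]
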