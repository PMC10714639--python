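"""State space, treatment strategies, transitions and per-cycle rewards.

Clinical course.  The monocular disease model tracks one eye through five
clinical states: NPDR (quiescent retinopathy under routine follow-up), PDR
(active neovascularisation, treated with panretinal photocoagulation or
anti-VEGF injections), DME (macular oedema, treated with anti-VEGF), SVL
(severe visual loss, visual acuity < 0.1, near-absorbing) and DEAD.

Attribute expansion.  The Markov property requires expanding the clinical
states with memory attributes: which treatment line applies to the next PDR
episode (for the two-line strategies), the last PDR therapy administered
(recurrence after anti-VEGF is 1.15x that after PRP), whether PRP was ever
given (a permanent peripheral-visual-field-defect disutility of 0.01), which
state a DME episode arose from (resolution returns the patient there), and
the SVL tenure year 1..5+ (injection continuation declines with tenure —
tunnel states).

Within-cycle ordering.  Death is applied first from the life table with the
diabetes/SVL relative risks; among survivors, PDR occupants are treated with
the current line's therapy with probability 0.8 (20% miss treatment that
cycle); cure moves the patient to NPDR, while uncured occupants (failed or
untreated) face the SVL (0.18) and DME (0.179) hazards.  A *failed* treated
cycle switches a two-line strategy to its second line.  Endophthalmitis is
folded in as a per-injection probability ``0.0006 * (1 - 0.595)`` of
transition to SVL for injection-receiving occupants plus an expected
treatment cost, rather than as an explicit state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .life_table import LifeTable, state_death_prob
from .params import ParameterSet, default_parameters

__all__ = [
    "NPDR", "PDR", "DME", "SVL", "DEAD", "PRP", "ANTIVEGF",
    "State", "StrategySpec", "STRATEGIES", "get_strategy", "INITIAL_STATE",
    "CycleRewards", "PERSPECTIVES",
    "build_state_space", "pdr_treatment_probs", "successors",
    "conditional_matrix", "transition_matrix", "death_vector",
    "cycle_rewards", "age_adjusted_utility", "utility_vector",
    "svl_continuation",
]

NPDR, PDR, DME, SVL, DEAD = "NPDR", "PDR", "DME", "SVL", "DEAD"
PRP, ANTIVEGF = "PRP", "antiVEGF"
FIRST, SECOND = "first", "second"

#: annual anti-VEGF injections: 3 (loading dose) per treated year in PDR and
#: DME; 2 per year in SVL, scaled by the tenure-year continuation probability
N_INJ_PDR = 3
N_INJ_DME = 3
N_INJ_SVL = 2

MIN_AGE, MAX_AGE = 50, 100
CARE_COST_AGE_CAP = 90  # care cost accrues in SVL only while age < 90

PERSPECTIVES = ("payer", "healthcare", "societal")
_COMPONENTS = ("covered", "noncovered", "glasses", "transport", "time", "care")
_PERSPECTIVE_COMPONENTS = {
    "payer": ("covered",),
    "healthcare": ("covered", "noncovered", "glasses"),
    "societal": _COMPONENTS,
}


class State(NamedTuple):
    """One attribute-expanded Markov state.

    ``line``/``last_tx`` are defined for NPDR/PDR/DME, ``dme_origin`` only for
    DME, ``svl_tenure`` (1..6, 6 meaning "after year 5") only for SVL.
    """

    clinical: str
    line: str | None = None
    last_tx: str | None = None
    ever_prp: bool = False
    dme_origin: str | None = None
    svl_tenure: int | None = None

    @property
    def label(self) -> str:
        if self.clinical == DEAD:
            return DEAD
        if self.clinical == SVL:
            return f"SVL|t={self.svl_tenure}|pvfd={int(self.ever_prp)}"
        parts = [self.clinical, f"line={self.line}", f"last={self.last_tx}",
                 f"pvfd={int(self.ever_prp)}"]
        if self.clinical == DME:
            parts.insert(1, f"from={self.dme_origin}")
        return "|".join(parts)


DEAD_STATE = State(DEAD)
INITIAL_STATE = State(PDR, line=FIRST, last_tx=None, ever_prp=False)


@dataclass(frozen=True)
class StrategySpec:
    """A treatment policy: which PDR therapy is used first and, if the first
    fails, second.  Single-therapy strategies never switch lines."""

    name: str
    first: str
    second: str | None = None

    @property
    def two_line(self) -> bool:
        return self.second is not None and self.second != self.first

    def therapy(self, line: str | None) -> str:
        if line == SECOND and self.two_line:
            return self.second  # type: ignore[return-value]
        return self.first


STRATEGIES: dict[str, StrategySpec] = {
    "prp-only": StrategySpec("prp-only", PRP),
    "antivegf-only": StrategySpec("antivegf-only", ANTIVEGF),
    "prp-first": StrategySpec("prp-first", PRP, ANTIVEGF),
    "antivegf-first": StrategySpec("antivegf-first", ANTIVEGF, PRP),
}


def get_strategy(strategy: str | StrategySpec) -> StrategySpec:
    if isinstance(strategy, StrategySpec):
        return strategy
    try:
        return STRATEGIES[strategy]
    except KeyError:
        raise ValueError(
            f"unknown strategy {strategy!r}; choose from {sorted(STRATEGIES)}"
        ) from None


def pdr_treatment_probs(therapy: str, params: ParameterSet) -> tuple[float, float]:
    """(success, recurrence) probabilities of a PDR therapy.

    Anti-VEGF effectiveness and recurrence are the PRP values scaled by their
    relative risks, capped at 1.
    """
    s, r = params.p_prp_success, params.p_recur_after_prp
    if therapy == PRP:
        return s, r
    if therapy == ANTIVEGF:
        return (min(1.0, s * params.rr_antivegf_effect),
                min(1.0, r * params.rr_antivegf_recur))
    raise ValueError(f"unknown therapy {therapy!r}")


def _endo_to_svl(params: ParameterSet, n_injections: float) -> float:
    """Per-cycle probability that endophthalmitis after the cycle's
    injections ends in SVL (incidence x failed treatment, per injection)."""
    return min(
        1.0,
        n_injections
        * params.p_endoph_per_injection
        * (1.0 - params.p_endoph_treat_success),
    )


def successors(state: State, strategy: StrategySpec, params: ParameterSet
               ) -> dict[State, float]:
    """Transition distribution out of ``state`` conditional on surviving the
    cycle.  Probabilities sum to 1; composition errors raise ValueError."""
    p = params
    c = state.clinical
    out: dict[State, float] = {}

    def add(s: State, w: float) -> None:
        if w != 0.0:
            out[s] = out.get(s, 0.0) + w

    if c == DEAD:
        return {DEAD_STATE: 1.0}

    if c == PDR:
        tx = strategy.therapy(state.line)
        success, _ = pdr_treatment_probs(tx, p)
        p_treat = 1.0 - p.p_loss_followup
        p_stay = 1.0 - p.p_pdr_to_svl - p.p_pdr_to_dme
        if p_stay < 0:
            raise ValueError("p_pdr_to_svl + p_pdr_to_dme exceeds 1")
        # untreated this cycle (loss to follow-up; redrawn every cycle)
        w = p.p_loss_followup
        add(State(SVL, ever_prp=state.ever_prp, svl_tenure=1), w * p.p_pdr_to_svl)
        add(State(DME, state.line, state.last_tx, state.ever_prp, dme_origin=PDR),
            w * p.p_pdr_to_dme)
        add(State(PDR, state.line, state.last_tx, state.ever_prp), w * p_stay)
        # treated this cycle
        ever = state.ever_prp or tx == PRP
        e = _endo_to_svl(p, N_INJ_PDR) if tx == ANTIVEGF else 0.0
        add(State(SVL, ever_prp=ever, svl_tenure=1), p_treat * e)
        add(State(NPDR, state.line, tx, ever), p_treat * (1.0 - e) * success)
        fail_line = (SECOND if strategy.two_line and state.line == FIRST
                     else state.line)
        w = p_treat * (1.0 - e) * (1.0 - success)
        add(State(SVL, ever_prp=ever, svl_tenure=1), w * p.p_pdr_to_svl)
        add(State(DME, fail_line, tx, ever, dme_origin=PDR), w * p.p_pdr_to_dme)
        add(State(PDR, fail_line, tx, ever), w * p_stay)

    elif c == NPDR:
        _, recur = pdr_treatment_probs(state.last_tx, p)
        stay = 1.0 - recur - p.p_npdr_to_dme
        if stay < 0:
            raise ValueError("NPDR recurrence + DME probability exceeds 1")
        add(State(PDR, state.line, state.last_tx, state.ever_prp), recur)
        add(State(DME, state.line, state.last_tx, state.ever_prp,
                  dme_origin=NPDR), p.p_npdr_to_dme)
        add(State(NPDR, state.line, state.last_tx, state.ever_prp), stay)

    elif c == DME:
        e = _endo_to_svl(p, N_INJ_DME)
        cure = p.p_dme_success
        add(State(SVL, ever_prp=state.ever_prp, svl_tenure=1), e)
        add(State(state.dme_origin, state.line, state.last_tx, state.ever_prp),
            (1.0 - e) * cure)
        add(State(DME, state.line, state.last_tx, state.ever_prp,
                  dme_origin=state.dme_origin), (1.0 - e) * (1.0 - cure))

    elif c == SVL:
        tenure = min((state.svl_tenure or 1) + 1, 6)
        add(State(SVL, ever_prp=state.ever_prp, svl_tenure=tenure), 1.0)

    else:
        raise ValueError(f"unknown clinical state {c!r}")

    total = sum(out.values())
    if any(w < -1e-15 or w > 1 + 1e-12 for w in out.values()) or abs(total - 1) > 1e-9:
        raise ValueError(
            f"transition mass out of {state.label} is inconsistent "
            f"(sum {total}); check parameter overrides"
        )
    return out


def build_state_space(strategy: str | StrategySpec) -> list[State]:
    """Enumerate all structurally reachable states for a strategy.

    Breadth-first closure from the initial PDR state under base parameters
    (every branch has positive probability at base, so this is the structural
    reachability set); DEAD is appended last.  Ordering is deterministic.
    """
    strategy = get_strategy(strategy)
    base = default_parameters()
    seen: dict[State, None] = {INITIAL_STATE: None}
    queue = [INITIAL_STATE]
    while queue:
        s = queue.pop(0)
        for nxt in successors(s, strategy, base):
            if nxt not in seen:
                seen[nxt] = None
                queue.append(nxt)
    states = [s for s in seen if s.clinical != DEAD]
    states.append(DEAD_STATE)
    return states


def death_vector(space: list[State], age: int, params: ParameterSet,
                 lt: LifeTable) -> np.ndarray:
    """Per-state annual death probability at ``age`` (0 for DEAD)."""
    q_gen = lt.q(age)
    return np.array(
        [0.0 if s.clinical == DEAD
         else state_death_prob(q_gen, params, is_svl=s.clinical == SVL)
         for s in space]
    )


def conditional_matrix(strategy: str | StrategySpec, params: ParameterSet,
                       space: list[State] | None = None) -> np.ndarray:
    """Row-stochastic transition matrix conditional on surviving the cycle."""
    strategy = get_strategy(strategy)
    if space is None:
        space = build_state_space(strategy)
    index = {s: i for i, s in enumerate(space)}
    n = len(space)
    m = np.zeros((n, n))
    for i, s in enumerate(space):
        for nxt, w in successors(s, strategy, params).items():
            try:
                m[i, index[nxt]] += w
            except KeyError:
                raise ValueError(
                    f"successor {nxt.label} of {s.label} not in state space"
                ) from None
    return m


def transition_matrix(strategy: str | StrategySpec, age: int,
                      params: ParameterSet, lt: LifeTable,
                      space: list[State] | None = None) -> np.ndarray:
    """Full row-stochastic annual transition matrix at ``age``.

    Death applies first; surviving mass follows :func:`conditional_matrix`.
    Rows sum to 1 within 1e-12.
    """
    strategy = get_strategy(strategy)
    if space is None:
        space = build_state_space(strategy)
    q = death_vector(space, age, params, lt)
    m = conditional_matrix(strategy, params, space) * (1.0 - q)[:, None]
    dead_idx = next(i for i, s in enumerate(space) if s.clinical == DEAD)
    m[:, dead_idx] += q
    if np.any(m < -1e-15) or np.any(m > 1 + 1e-12):
        raise ValueError("transition probability outside [0, 1]; "
                         "check parameter overrides")
    if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-12:
        raise ValueError("transition matrix rows do not sum to 1")
    return m


def svl_continuation(params: ParameterSet, tenure: int) -> float:
    """Probability of continuing twice-yearly injections in SVL, by tenure
    year (1..5, then a constant 'after year 5' value)."""
    keys = ["y1", "y2", "y3", "y4", "y5", "y5plus"]
    return params[f"svl_continuation_{keys[min(tenure, 6) - 1]}"]


def age_adjusted_utility(clinical: str, age: float, params: ParameterSet) -> float:
    """State utility at a given age.

    The published utilities are age ranges: the upper value applies at age 50
    and falls linearly to the lower value at age 100 (a span of 0.055 for all
    states).  Anchors above 1 (possible in sensitivity analyses) are censored
    to 1 before the decline is applied.
    """
    if not MIN_AGE <= age <= MAX_AGE:
        raise ValueError(f"age {age} outside [{MIN_AGE}, {MAX_AGE}]")
    if clinical == DEAD:
        return 0.0
    anchor = min(1.0, params[f"u_{clinical.lower()}"])
    u = anchor - params.utility_age_decline * (age - MIN_AGE) / (MAX_AGE - MIN_AGE)
    return float(min(1.0, max(0.0, u)))


def utility_vector(space: list[State], age: float, params: ParameterSet) -> np.ndarray:
    """Vectorised per-state utility at ``age``: the age-adjusted clinical
    utility minus the permanent pVFD disutility where PRP was ever given,
    floored at 0 (DEAD contributes 0)."""
    if not MIN_AGE <= age <= MAX_AGE:
        raise ValueError(f"age {age} outside [{MIN_AGE}, {MAX_AGE}]")
    shift = params.utility_age_decline * (age - MIN_AGE) / (MAX_AGE - MIN_AGE)
    anchors = np.array(
        [0.0 if s.clinical == DEAD else min(1.0, params[f"u_{s.clinical.lower()}"])
         for s in space]
    )
    living = np.array([s.clinical != DEAD for s in space], dtype=float)
    u = np.clip(anchors - shift * living, 0.0, 1.0)
    pvfd = np.array([s.ever_prp for s in space], dtype=float)
    return np.maximum(0.0, u - params.disutility_pvfd * pvfd * living)


@dataclass
class CycleRewards:
    """Per-state annual cost components and utilities for one cycle.

    ``components`` maps component name (covered, noncovered, glasses,
    transport, time, care) to a per-state array; expected endophthalmitis
    treatment costs are folded into the four medical/indirect components.
    """

    space: list[State]
    components: dict[str, np.ndarray]
    utility: np.ndarray

    def cost(self, perspective: str) -> np.ndarray:
        """Per-state annual cost under a perspective (payer: covered only;
        healthcare: + non-covered and glasses; societal: everything)."""
        try:
            keys = _PERSPECTIVE_COMPONENTS[perspective]
        except KeyError:
            raise ValueError(f"unknown perspective {perspective!r}") from None
        return sum(self.components[k] for k in keys)  # type: ignore[return-value]


def _episode_cost(params: ParameterSet, block: str) -> dict[str, float]:
    return {comp: params[f"cost_{block}_{comp}"]
            for comp in ("covered", "noncovered", "transport", "time")}


def cycle_rewards(strategy: str | StrategySpec, age: int, params: ParameterSet,
                  space: list[State] | None = None) -> CycleRewards:
    """Annual cost components and utility for every state at ``age``.

    State occupancy bills the state's annual cost; PDR occupants additionally
    bill the current line's therapy for the treated 80% (one PRP episode, or
    three anti-VEGF injections); DME bills three injections; SVL bills two
    injections weighted by the tenure-year continuation probability, plus a
    daily-care cost while age < 90 and low-vision glasses.  Every injection
    adds an expected endophthalmitis treatment cost.

    Coverage follows the Korean reimbursement rules the strategies are built
    around: anti-VEGF injections given for PDR are not NHIS-covered (their
    whole episode cost is non-covered medical cost, so the payer perspective
    excludes them), whereas injections for DME and the claims-observed SVL
    continuation injections use the published covered/non-covered split.

    Utility is the
    age-adjusted state utility minus the permanent 0.01 pVFD disutility if
    PRP was ever given, floored at 0.
    """
    strategy = get_strategy(strategy)
    if space is None:
        space = build_state_space(strategy)
    p = params
    n = len(space)
    comp = {k: np.zeros(n) for k in _COMPONENTS}
    utility = utility_vector(space, age, p)
    prp_ep = _episode_cost(p, "prp")
    inj_ep = _episode_cost(p, "inj")
    endo_ep = _episode_cost(p, "endoph")

    for i, s in enumerate(space):
        if s.clinical == DEAD:
            continue
        state_block = s.clinical.lower()
        for c in ("covered", "noncovered", "transport", "time"):
            comp[c][i] += p[f"cost_{state_block}_{c}"]
        n_inj = 0.0
        inj_noncovered = False
        if s.clinical == PDR:
            tx = strategy.therapy(s.line)
            treated = 1.0 - p.p_loss_followup
            if tx == PRP:
                for c, v in prp_ep.items():
                    comp[c][i] += treated * v
            else:
                n_inj = treated * N_INJ_PDR
                # anti-VEGF is not NHIS-reimbursed for PDR (only PRP is), so
                # the injection's covered component is borne by the patient:
                # it counts as non-covered medical cost for this indication
                inj_noncovered = True
        elif s.clinical == DME:
            n_inj = float(N_INJ_DME)
        elif s.clinical == SVL:
            n_inj = N_INJ_SVL * svl_continuation(p, s.svl_tenure or 1)
            comp["glasses"][i] += p.cost_svl_glasses
            if age < CARE_COST_AGE_CAP:
                comp["care"][i] += p.cost_svl_care
        if n_inj:
            for c, v in inj_ep.items():
                if c == "covered" and inj_noncovered:
                    c = "noncovered"
                comp[c][i] += n_inj * v
            # expected endophthalmitis treatment cost per injection given
            # (complication care is reimbursed regardless of indication)
            for c, v in endo_ep.items():
                comp[c][i] += n_inj * p.p_endoph_per_injection * v
    return CycleRewards(space, comp, utility)
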