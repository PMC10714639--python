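"""Synthetic stand-ins for the model's non-public inputs.

The cost and utility inputs of the published model come from national claims
data (macro-costing of per-state annual costs) and a 300-patient EQ-5D
survey, neither of which is distributable.  This module generates
claims-like per-patient episode records with gamma-distributed costs and
EQ-5D-like per-state utility responses so that the estimation stage —
macro-costing per state-year and per-state mean utilities — is exercisable
and testable end to end.  Dispersion choices (gamma CV 0.8, utility SD 0.08)
are configurable stand-ins; only the means are anchored to the model's
inputs.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .params import ParameterSet

__all__ = [
    "COST_COMPONENTS",
    "state_cost_means",
    "state_utility_means",
    "synth_claims_episodes",
    "macro_costing",
    "synth_eq5d_survey",
    "estimate_state_utilities",
]

LIVING_STATES = ("NPDR", "PDR", "DME", "SVL")
COST_COMPONENTS = ("covered", "noncovered", "transport", "time", "care")

DEFAULT_COST_CV = 0.8  #: per-record gamma coefficient of variation
DEFAULT_UTILITY_SD = 0.08  #: per-respondent utility standard deviation


def state_cost_means(params: ParameterSet) -> dict[str, dict[str, float]]:
    """Per-state annual cost-component means implied by a parameter set."""
    out: dict[str, dict[str, float]] = {}
    for state in LIVING_STATES:
        block = state.lower()
        means = {c: params[f"cost_{block}_{c}"]
                 for c in ("covered", "noncovered", "transport", "time")}
        means["care"] = params.cost_svl_care if state == "SVL" else 0.0
        out[state] = means
    return out


def state_utility_means(params: ParameterSet) -> dict[str, float]:
    """Per-state mean utilities (midpoint of the published age range)."""
    return {
        state: min(1.0, params[f"u_{state.lower()}"]) - params.utility_age_decline / 2
        for state in LIVING_STATES
    }


def synth_claims_episodes(
    state_means: Mapping[str, Mapping[str, float]],
    n_patient_years: int,
    seed: int,
    cv: float = DEFAULT_COST_CV,
) -> pd.DataFrame:
    """Claims-like cost records: ``n_patient_years`` rows per state.

    Each record carries one patient-year in one Markov state with
    component-wise costs drawn independently from gamma distributions with
    the given means and coefficient of variation ``cv``.  Zero means yield
    exactly-zero costs.  Deterministic under ``seed``.
    """
    if n_patient_years < 0:
        raise ValueError("n_patient_years must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    shape = 1.0 / cv**2 if cv > 0 else None
    for state in state_means:
        means = state_means[state]
        if any(m < 0 for m in means.values()):
            raise ValueError(f"negative cost mean for state {state}")
        for year in range(n_patient_years):
            rec = {"patient_id": pid, "state": state, "year": year}
            for comp in COST_COMPONENTS:
                m = float(means.get(comp, 0.0))
                if m == 0.0:
                    rec[comp] = 0.0
                elif shape is None:
                    rec[comp] = m
                else:
                    rec[comp] = float(rng.gamma(shape, m / shape))
            rows.append(rec)
            pid += 1
    return pd.DataFrame(
        rows, columns=["patient_id", "state", "year", *COST_COMPONENTS]
    )


def macro_costing(records: pd.DataFrame) -> pd.DataFrame:
    """Macro-costing estimator: mean annual cost per state and component.

    Total component cost divided by patient-years in the state, with a
    standard error per component.  States with zero patient-years are
    omitted with a warning.
    """
    if records.empty:
        warnings.warn("no episode records; nothing to estimate")
        return pd.DataFrame(columns=["state", "n"])
    out = []
    for state, grp in records.groupby("state", sort=False):
        n = len(grp)
        row = {"state": state, "n": n}
        for comp in COST_COMPONENTS:
            if comp not in grp:
                continue
            row[comp] = float(grp[comp].mean())
            row[f"{comp}_se"] = (
                float(grp[comp].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            )
        out.append(row)
    return pd.DataFrame(out).set_index("state")


def synth_eq5d_survey(
    state_means: Mapping[str, float],
    n: int = 300,
    seed: int = 0,
    sd: float = DEFAULT_UTILITY_SD,
) -> pd.DataFrame:
    """EQ-5D-like utility responses: ``n`` respondents per state.

    Responses are drawn from a beta distribution matched by method of moments
    to the state mean and ``sd``, censored to [0, 1]; ``sd = 0`` returns the
    mean exactly.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    rid = 0
    for state, m in state_means.items():
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"utility mean for {state} outside [0, 1]")
        for _ in range(n):
            if sd <= 0 or m in (0.0, 1.0):
                u = m
            else:
                nu = m * (1 - m) / sd**2 - 1.0
                if nu <= 0:
                    raise ValueError(
                        f"utility SD {sd} too large for mean {m} (state {state})"
                    )
                u = float(np.clip(rng.beta(m * nu, (1 - m) * nu), 0.0, 1.0))
            rows.append({"respondent_id": rid, "state": state, "utility": u})
            rid += 1
    return pd.DataFrame(rows, columns=["respondent_id", "state", "utility"])


def estimate_state_utilities(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-state mean utility and standard error from survey responses."""
    if responses.empty:
        raise ValueError("no survey responses")
    out = []
    for state, grp in responses.groupby("state", sort=False):
        n = len(grp)
        out.append({
            "state": state,
            "n": n,
            "utility": float(grp["utility"].mean()),
            "utility_se": (
                float(grp["utility"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            ),
        })
    return pd.DataFrame(out).set_index("state")
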