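"""Model parameters: canonical table, validation, file loading and PSA samplers.

The model is driven by a flat set of named scalar parameters: Markov transition
probabilities, mortality relative risks, per-state annual costs and per-episode
treatment costs split by component (NHIS-covered, non-covered, transportation,
patient time, care), health-state utilities and the annual discount rate.  Every
parameter carries deterministic sensitivity bounds and, where applicable, a
probabilistic-sensitivity-analysis distribution family:

* probabilities           -> beta (method of moments) or symmetric triangle
* relative risks          -> lognormal, sigma recovered from the published 95% CI
* cost components         -> gamma (method of moments)
* utilities               -> triangle on the age-50 anchor, censored at 1

For beta/gamma families the published +/-20% range is interpreted as a 95%
interval, giving ``SE = 0.20 * base / 1.96``; parameters drawn outside their
domain are resampled (rejection) rather than clipped, except utilities which
are censored at 1.  Parameters without a usable dispersion spec are held fixed
in the PSA.  Joint draws are independent across parameters.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "Parameter",
    "ParameterSet",
    "ParameterError",
    "Sampler",
    "default_parameters",
    "load_parameters",
    "build_sampler",
    "sample_parameter_set",
    "canonical_table",
]

#: published +/- range used for most parameters, as a fraction of the base value
PCT_RANGE = 0.20
#: the +/-20% range is read as a 95% interval when building beta/gamma samplers
Z_95 = 1.96


class ParameterError(ValueError):
    """Raised for unknown names, schema violations or out-of-range values."""


@dataclass(frozen=True)
class Parameter:
    """One named model input with its sensitivity-analysis metadata.

    ``range_kind`` records how the DSA bounds were specified: ``"pct"`` for the
    +/-20% rule (bounds rescale if the base is overridden), ``"explicit"`` for
    printed bounds (discount rate, pVFD disutility), ``"ci"`` for relative
    risks varied over their 95% CI, and ``"none"`` for unranged parameters.
    """

    name: str
    base: float
    units: str  # probability | relative-risk | usd | utility | rate
    dist: str = "fixed"  # beta | gamma | lognormal | triangle | fixed
    range_kind: str = "pct"
    low: float | None = None
    high: float | None = None
    ci: tuple[float, float] | None = None

    def raw_bounds(self) -> tuple[float, float] | None:
        """Range bounds before any domain censoring, or None if unranged."""
        if self.range_kind == "none":
            return None
        if self.range_kind == "ci":
            lo, hi = self.ci  # type: ignore[misc]
        elif self.range_kind == "explicit":
            lo, hi = self.low, self.high  # type: ignore[assignment]
        else:  # pct
            lo, hi = self.base * (1 - PCT_RANGE), self.base * (1 + PCT_RANGE)
        return float(lo), float(hi)

    def dsa_bounds(self) -> tuple[float, float] | None:
        """Deterministic one-way sensitivity bounds, or None if unranged.

        Probability- and utility-typed bounds are censored to [0, 1] so that
        a bound produced by the +/-20% rule can never leave the domain (the
        PSA sampler instead censors or rejects individual draws).
        """
        bounds = self.raw_bounds()
        if bounds is None:
            return None
        lo, hi = bounds
        if self.units in ("probability", "utility"):
            lo, hi = max(0.0, lo), min(1.0, hi)
        return float(lo), float(hi)

    def with_base(self, value: float) -> "Parameter":
        """Return a copy recentred on ``value`` (pct ranges rescale with it)."""
        return replace(self, base=float(value))

    def validate_value(self, value: float) -> None:
        if not np.isfinite(value):
            raise ParameterError(f"{self.name}: value {value!r} is not finite")
        if self.units == "probability" and not 0.0 <= value <= 1.0:
            raise ParameterError(
                f"{self.name}: probability {value} outside [0, 1]"
            )
        if self.units == "usd" and value < 0:
            raise ParameterError(f"{self.name}: cost {value} is negative")
        if self.units == "relative-risk" and value <= 0:
            raise ParameterError(f"{self.name}: relative risk {value} must be > 0")
        if self.units == "utility" and not 0.0 <= value <= 1.0:
            raise ParameterError(f"{self.name}: utility {value} outside [0, 1]")
        if self.units == "rate" and value < 0:
            raise ParameterError(f"{self.name}: rate {value} is negative")


def _p(name, base, units, dist="fixed", range_kind="pct", low=None, high=None, ci=None):
    return Parameter(name, base, units, dist, range_kind, low, high, ci)


def _build_table() -> dict[str, Parameter]:
    t: list[Parameter] = []
    # --- Markov transition probabilities -----------------------------------
    t += [
        _p("p_npdr_to_dme", 0.1522, "probability", "beta"),
        _p("p_pdr_to_dme", 0.179, "probability", "beta"),
        _p("p_pdr_to_svl", 0.18, "probability", "triangle"),
        _p("p_prp_success", 0.2008, "probability", "beta"),
        _p("p_recur_after_prp", 0.0169, "probability", "beta"),
        _p("p_dme_success", 0.534, "probability", "beta"),
        _p("p_endoph_per_injection", 0.0006, "probability", "beta"),
        _p("p_endoph_treat_success", 0.595, "probability", "beta"),
        _p("p_loss_followup", 0.2, "probability", "triangle"),
    ]
    # anti-VEGF injection continuation in the SVL state, by tenure year
    for key, v in [("y1", 0.914), ("y2", 0.736), ("y3", 0.65),
                   ("y4", 0.609), ("y5", 0.537), ("y5plus", 0.481)]:
        t.append(_p(f"svl_continuation_{key}", v, "probability", "fixed"))
    t.append(_p("discount_rate", 0.045, "rate", "fixed", "explicit", 0.03, 0.07))
    # --- relative risks -----------------------------------------------------
    t += [
        _p("rr_antivegf_effect", 1.75, "relative-risk", "lognormal", "ci",
           ci=(1.12, 2.75)),
        _p("rr_antivegf_recur", 1.15, "relative-risk", "lognormal", "ci",
           ci=(0.63, 2.12)),
        _p("rr_death_diabetes", 1.49, "relative-risk", "lognormal", "ci",
           ci=(1.45, 1.54)),
        # no interval is published for the SVL mortality ratio -> held fixed
        _p("rr_death_svl", 11.54, "relative-risk", "fixed", "none"),
    ]
    # --- annual per-state and per-episode costs (2020 USD) ------------------
    cost_blocks = {
        "npdr": dict(covered=160, noncovered=12, transport=4, time=82),
        "pdr": dict(covered=348, noncovered=44, transport=10, time=147),
        "dme": dict(covered=1732, noncovered=267, transport=24, time=375),
        "svl": dict(covered=338, noncovered=49, transport=12, time=162),
        "prp": dict(covered=188, noncovered=24, transport=2, time=32),
        "inj": dict(covered=447, noncovered=63, transport=2, time=25),
        "endoph": dict(covered=2143, noncovered=1208, transport=2, time=232),
    }
    for block, comps in cost_blocks.items():
        for comp, v in comps.items():
            t.append(_p(f"cost_{block}_{comp}", float(v), "usd", "gamma"))
    t.append(_p("cost_svl_care", 11826.0, "usd", "gamma"))
    t.append(_p("cost_svl_glasses", 27.0, "usd", "gamma"))
    # --- utilities (age-50 anchors; decline reaches the lower printed value
    # at age 100: 0.904->0.849 etc., a shared span of 0.055) -----------------
    t += [
        _p("u_npdr", 0.904, "utility", "triangle"),
        _p("u_pdr", 0.901, "utility", "triangle"),
        _p("u_dme", 0.912, "utility", "triangle"),
        _p("u_svl", 0.851, "utility", "triangle"),
        _p("utility_age_decline", 0.055, "utility", "fixed", "none"),
        _p("disutility_pvfd", 0.01, "utility", "fixed", "explicit", 0.005, 0.02),
    ]
    t.append(_p("wtp_threshold", 24400.0, "usd", "fixed", "none"))
    return {p.name: p for p in t}


_CANONICAL: dict[str, Parameter] = _build_table()


def canonical_table() -> dict[str, Parameter]:
    """A fresh copy of the canonical parameter table (base-case Table values)."""
    return copy.deepcopy(_CANONICAL)


class ParameterSet:
    """A complete, validated mapping of parameter name -> numeric value.

    Values are exposed as attributes (``ps.p_prp_success``) and via
    ``ps["name"]``.  Each set carries its own copy of the parameter table so
    that overrides recentre sampler construction and DSA bounds, plus a
    provenance tag (``base``, ``dsa-low``, ``dsa-high`` or ``psa-draw``) and
    the seed used if the set was sampled.
    """

    def __init__(
        self,
        values: Mapping[str, float],
        table: Mapping[str, Parameter] | None = None,
        provenance: str = "base",
        seed: int | None = None,
        validate: bool = True,
    ):
        table = dict(table) if table is not None else canonical_table()
        unknown = set(values) - set(table)
        if unknown:
            raise ParameterError(f"unknown parameter {sorted(unknown)[0]!r}")
        missing = set(table) - set(values)
        if missing:
            raise ParameterError(
                f"incomplete parameter set; missing {sorted(missing)!r}"
            )
        vals = {name: float(values[name]) for name in table}
        if validate:
            for name, v in vals.items():
                table[name].validate_value(v)
        object.__setattr__(self, "_values", vals)
        object.__setattr__(self, "table", table)
        object.__setattr__(self, "provenance", provenance)
        object.__setattr__(self, "seed", seed)

    # -- mapping / attribute access -----------------------------------------
    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __getattr__(self, name: str) -> float:
        try:
            return self.__dict__["_values"][name]
        except KeyError:
            raise AttributeError(name) from None

    def __iter__(self):
        return iter(self._values)

    def __len__(self):
        return len(self._values)

    def __eq__(self, other):
        return isinstance(other, ParameterSet) and self._values == other._values

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def names(self) -> list[str]:
        return list(self._values)

    # -- derived sets --------------------------------------------------------
    def with_values(self, provenance: str = "override", **overrides: float) -> "ParameterSet":
        """A new set with the given overrides; pct DSA ranges recentre."""
        vals = dict(self._values)
        table = dict(self.table)
        for name, v in overrides.items():
            if name not in table:
                raise ParameterError(f"unknown parameter {name!r}")
            vals[name] = float(v)
            table[name] = table[name].with_base(float(v))
        return ParameterSet(vals, table, provenance=provenance)

    def __repr__(self):
        return (f"ParameterSet({len(self)} parameters, "
                f"provenance={self.provenance!r})")


def default_parameters() -> ParameterSet:
    """The full base-case parameter set, exactly as published."""
    table = canonical_table()
    return ParameterSet({n: p.base for n, p in table.items()}, table, "base")


def load_parameters(path: str | Path, fill_defaults: bool = False) -> ParameterSet:
    """Load a flat ``name: value`` YAML parameter file.

    Unknown keys are rejected; missing keys are an error unless
    ``fill_defaults`` is set, in which case they take their base-case values.
    An optional ``distributions`` block may override a parameter's PSA family
    (``dist``) and/or 95% CI (``ci: [lo, hi]``).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParameterError("parameter file must be a mapping of name: value")
    dist_block = raw.pop("distributions", {}) or {}
    table = canonical_table()

    for name in raw:
        if name not in table:
            raise ParameterError(f"unknown parameter {name!r}")
        if not isinstance(raw[name], (int, float)) or isinstance(raw[name], bool):
            raise ParameterError(f"{name!r}: value must be numeric")
        table[name] = table[name].with_base(float(raw[name]))

    for name, spec in dist_block.items():
        if name not in table:
            raise ParameterError(f"distributions: unknown parameter {name!r}")
        p = table[name]
        if "dist" in spec:
            p = replace(p, dist=str(spec["dist"]))
        if "ci" in spec:
            lo, hi = spec["ci"]
            p = replace(p, ci=(float(lo), float(hi)), range_kind="ci")
        table[name] = p

    values = {n: p.base for n, p in table.items()}
    if not fill_defaults:
        missing = set(table) - set(raw)
        if missing:
            raise ParameterError(
                "parameter file is missing "
                f"{sorted(missing)[0]!r} (and {len(missing) - 1} more); "
                "pass fill_defaults=True to take base-case values"
            )
    return ParameterSet(values, table, provenance="file")


# ---------------------------------------------------------------------------
# PSA samplers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sampler:
    """A constructed PSA distribution for one parameter.

    ``family`` is one of beta/gamma/lognormal/triangle/fixed and ``args``
    holds the family's parameters (``a``/``b`` for beta, ``shape``/``scale``
    for gamma, ``mu``/``sigma`` for lognormal, ``left``/``mode``/``right``
    for triangle, ``value`` for fixed).
    """

    family: str
    args: dict[str, float] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        a = self.args
        if self.family == "fixed":
            return a["value"]
        if self.family == "beta":
            return a["a"] / (a["a"] + a["b"])
        if self.family == "gamma":
            return a["shape"] * a["scale"]
        if self.family == "lognormal":
            return math.exp(a["mu"] + a["sigma"] ** 2 / 2)
        if self.family == "triangle":
            return (a["left"] + a["mode"] + a["right"]) / 3.0
        raise ValueError(self.family)

    def draw(self, rng: np.random.Generator, size=None):
        a = self.args
        if self.family == "fixed":
            return a["value"] if size is None else np.full(size, a["value"])
        if self.family == "beta":
            return rng.beta(a["a"], a["b"], size=size)
        if self.family == "gamma":
            return rng.gamma(a["shape"], a["scale"], size=size)
        if self.family == "lognormal":
            return rng.lognormal(a["mu"], a["sigma"], size=size)
        if self.family == "triangle":
            if a["left"] == a["right"]:
                return a["mode"] if size is None else np.full(size, a["mode"])
            return rng.triangular(a["left"], a["mode"], a["right"], size=size)
        raise ValueError(self.family)


def build_sampler(param: Parameter) -> Sampler:
    """Construct the PSA sampler for one parameter.

    Beta and gamma use method of moments with mean = base and
    SE = 0.20*base/1.96 (the +/-20% range read as a 95% interval); lognormal
    uses mu = ln(base) and sigma = (ln hi - ln lo)/(2*1.96) from the 95% CI;
    triangle uses mode = base with the DSA bounds as support.
    """
    base = param.base
    if param.dist == "fixed":
        return Sampler("fixed", {"value": base})
    if param.dist == "beta":
        if not 0.0 < base < 1.0:
            return Sampler("fixed", {"value": base})
        se = PCT_RANGE * base / Z_95
        nu = base * (1.0 - base) / se**2 - 1.0
        if nu <= 0:
            raise ParameterError(
                f"{param.name}: beta method of moments infeasible (SE too large)"
            )
        return Sampler("beta", {"a": base * nu, "b": (1.0 - base) * nu})
    if param.dist == "gamma":
        if base < 0:
            raise ParameterError(f"{param.name}: gamma requires base >= 0")
        if base == 0:
            return Sampler("fixed", {"value": 0.0})
        se = PCT_RANGE * base / Z_95
        shape = (base / se) ** 2
        return Sampler("gamma", {"shape": shape, "scale": base / shape})
    if param.dist == "lognormal":
        if base <= 0:
            raise ParameterError(f"{param.name}: lognormal requires base > 0")
        if param.ci is None:
            raise ParameterError(f"{param.name}: lognormal requires a 95% CI")
        lo, hi = param.ci
        sigma = (math.log(hi) - math.log(lo)) / (2.0 * Z_95)
        return Sampler("lognormal", {"mu": math.log(base), "sigma": sigma})
    if param.dist == "triangle":
        # full +/-20% support; out-of-domain draws are censored (utilities)
        # or rejected (probabilities) at sampling time, not truncated here
        lo, hi = param.raw_bounds() or (base, base)
        return Sampler("triangle", {"left": lo, "mode": base, "right": hi})
    raise ParameterError(f"{param.name}: unknown distribution {param.dist!r}")


_MAX_REJECT = 1000


def sample_parameter_set(
    base: ParameterSet, seed: int | np.random.Generator
) -> ParameterSet:
    """One joint PSA draw, independent across parameters.

    Probabilities falling outside [0, 1] are resampled rather than clipped,
    preserving the constructed family; utilities are censored at 1 (the
    published rule).  Deterministic under the supplied seed or generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_tag = None if isinstance(seed, np.random.Generator) else int(seed)
    values: dict[str, float] = {}
    for name, param in base.table.items():
        sampler = build_sampler(param)
        v = float(sampler.draw(rng))
        if param.units == "probability":
            tries = 0
            while not 0.0 <= v <= 1.0:
                v = float(sampler.draw(rng))
                tries += 1
                if tries > _MAX_REJECT:
                    raise ParameterError(
                        f"{name}: rejection sampling failed to land in [0, 1]"
                    )
        elif param.units == "utility":
            v = min(v, 1.0)
        elif param.units in ("usd", "relative-risk"):
            tries = 0
            while v < 0 or (param.units == "relative-risk" and v <= 0):
                v = float(sampler.draw(rng))
                tries += 1
                if tries > _MAX_REJECT:
                    raise ParameterError(f"{name}: rejection sampling failed")
        values[name] = v
    return ParameterSet(values, base.table, provenance="psa-draw", seed=seed_tag)
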