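"""Deterministic sensitivity analysis: one-way (tornado), threshold search,
and scenario runs.

One-way analysis re-evaluates a pairwise ICER with a single parameter at the
low and high ends of its range (reported 95% CI, else +/-10%; +/-30% for
costs) while everything else stays at base case; entries sorted by swing give
the tornado ordering.  Threshold search inverts the ICER in one parameter by
bisection.  Scenarios re-evaluate all three strategies under a named override
mapping and report the Table-style row (three costs, three QALYs, three
pairwise ICERs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.optimize import brentq

from . import params as params_mod
from .params import ParameterSet, UncertainParameter, interval_for
from .tree import evaluate_strategy, STRATEGIES
from .cea import icer

__all__ = [
    "TornadoEntry", "ScenarioSpec", "one_way", "tornado",
    "threshold_search", "run_scenario", "bundled_scenarios",
    "Comparison", "parse_comparison",
]

#: (comparator, reference) pairs reported throughout
PAIRWISE = (
    ("population_based", "symptom_only"),
    ("population_based", "fh_based"),
    ("fh_based", "symptom_only"),
)


@dataclass(frozen=True)
class Comparison:
    comparator: str
    reference: str


def parse_comparison(text: str) -> Comparison:
    """Parse "comparator:reference" (e.g. "population_based:symptom_only")."""
    try:
        comp, ref = text.split(":")
    except ValueError:
        raise ValueError(f"comparison must be 'comparator:reference', got {text!r}")
    for name in (comp, ref):
        if name not in STRATEGIES:
            raise ValueError(f"unknown strategy {name!r}")
    return Comparison(comp, ref)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    overrides: dict[str, float] = field(default_factory=dict)
    description: str = ""


def _pair_icer(comparison: Comparison, params: ParameterSet) -> float:
    ref = evaluate_strategy(comparison.reference, params)
    comp = evaluate_strategy(comparison.comparator, params)
    return icer(ref, comp, params.wtp).icer


_UPTAKE_FIELDS = ("p20", "p26", "p32", "p38")


def _feasible(name: str, value: float, params: ParameterSet) -> float:
    """Cap a one-way variation so the parameter set stays structurally valid.

    Varying a single uptake rate to its CI end can push the four uptakes past
    a total of 1; the varied value is capped so the surveillance residual
    stays non-negative (the other three rates are untouched).  Analogously,
    p50/p51/p1 variations are capped to keep the detected family-history
    carrier mass within the total prevalence in coherent mode.
    """
    if name in _UPTAKE_FIELDS:
        others = sum(getattr(params, f) for f in _UPTAKE_FIELDS if f != name)
        return min(value, 1.0 - others)
    if params.fh_detection_convention == "coherent":
        if name == "p50" and params.p51 > 0:
            return min(value, params.p1 / params.p51)
        if name == "p51" and params.p50 > 0:
            return min(value, params.p1 / params.p50)
        if name == "p1":
            return max(value, params.p50 * params.p51)
    return value


def one_way(parameter: str | UncertainParameter, comparison: Comparison,
            params: ParameterSet) -> TornadoEntry:
    """ICER with one parameter at each end of its range, all else base case."""
    if isinstance(parameter, str):
        parameter = params_mod.uncertain_parameters(params)[parameter]
    low, high = interval_for(parameter)
    low = _feasible(parameter.name, low, params)
    high = _feasible(parameter.name, high, params)
    return TornadoEntry(
        parameter.name, low, high,
        _pair_icer(comparison, params.replace(**{parameter.name: low})),
        _pair_icer(comparison, params.replace(**{parameter.name: high})),
    )


def tornado(comparison: Comparison, params: ParameterSet,
            roster: list[str] | None = None) -> list[TornadoEntry]:
    """One-way entries for the full varied-parameter roster, by swing."""
    specs = params_mod.uncertain_parameters(params)
    names = roster if roster is not None else list(specs)
    entries = [one_way(specs[name], comparison, params) for name in names]
    return sorted(entries, key=lambda e: -e.swing)


def threshold_search(parameter: str, comparison: Comparison,
                     target_icer: float, bracket: tuple[float, float],
                     params: ParameterSet, tol: float = 0.5,
                     max_iter: int = 200) -> float:
    """Parameter value at which the pairwise ICER crosses ``target_icer``.

    Bisection (Brent) on ICER(parameter) - target within ``bracket``;
    the result satisfies |ICER - target| < ``tol`` yuan/QALY.
    """
    def f(x: float) -> float:
        return _pair_icer(comparison, params.replace(**{parameter: x})) - target_icer

    f_lo, f_hi = f(bracket[0]), f(bracket[1])
    if f_lo * f_hi > 0:
        raise ValueError(
            f"ICER does not cross {target_icer} for {parameter} in "
            f"{bracket}: endpoints give {f_lo + target_icer:.1f} and "
            f"{f_hi + target_icer:.1f}"
        )
    x = brentq(f, *bracket, xtol=1e-10, rtol=8.9e-16, maxiter=max_iter)
    resid = abs(f(x))
    if resid >= tol:
        raise ValueError(
            f"threshold search did not converge: |ICER - target| = {resid:.3g}"
        )
    return float(x)


def run_scenario(spec: ScenarioSpec, params: ParameterSet) -> dict[str, float]:
    """Evaluate all three strategies under a scenario's overrides.

    Returns a flat mapping: cost and QALY per strategy plus the three
    pairwise ICERs (signed values, as exported).
    """
    scenario_params = params_mod.overrides_from_mapping(params, spec.overrides)
    results = {s: evaluate_strategy(s, scenario_params) for s in STRATEGIES}
    row: dict[str, float] = {}
    for s in STRATEGIES:
        row[f"cost_{s}"] = results[s].expected_cost
        row[f"qaly_{s}"] = results[s].expected_qaly
    for comp, ref in PAIRWISE:
        row[f"icer_{comp}_vs_{ref}"] = icer(
            results[ref], results[comp], scenario_params.wtp).icer
    return row


def bundled_scenarios() -> dict[str, ScenarioSpec]:
    """The published scenario set (plus the low-test-cost break-even rows)."""
    specs = [
        ScenarioSpec("brca_test_1878", {"cost_brca_test": 1878.0},
                     "BRCA test cost cut 48% to the population-based break-even point"),
        ScenarioSpec("brca_test_1808", {"cost_brca_test": 1808.0},
                     "BRCA test cost cut 50%"),
        ScenarioSpec("p15_lifetime", {"p15": 0.202},
                     "lifetime (not to-age-70) ovarian-cancer risk in carriers"),
        ScenarioSpec("p16_lifetime", {"p16": 0.644},
                     "lifetime breast-cancer risk in carriers"),
        ScenarioSpec("lifetime_both", {"p15": 0.202, "p16": 0.644},
                     "lifetime risks for both cancers"),
        ScenarioSpec("fh_rate_china", {"p50": 0.032},
                     "highest reported Chinese family-history positivity rate"),
        ScenarioSpec("p1_us", {"p1": 0.00677},
                     "US-level BRCA1/2 population prevalence"),
    ]
    return {s.name: s for s in specs}
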