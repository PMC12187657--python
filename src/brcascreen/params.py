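"""Model parameters for the BRCA1/2 screening cost-effectiveness model.

A :class:`ParameterSet` is the single source of truth for every quantity the
decision trees consume: prevalences, cancer penetrances, uptake rates of
risk-reducing interventions, intervention risk ratios, health-state
utilities, 10-year survival proportions, unit costs (Chinese yuan), the
analytic horizon and the willingness-to-pay threshold.

Each parameter additionally carries an uncertainty specification
(:class:`UncertainParameter`) used by the deterministic and probabilistic
sensitivity analyses: a 95% confidence interval where one is reported, and
otherwise a conventional +/-10% range (+/-30% for unit costs).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "ParameterSet",
    "UncertainParameter",
    "default_parameters",
    "uncertain_parameters",
    "interval_for",
    "validate",
    "load_config",
    "save_config",
    "ConfigError",
    "PROBABILITY_FIELDS",
    "UTILITY_FIELDS",
    "SURVIVAL_FIELDS",
    "COST_FIELDS",
]

#: fields bounded to [0, 1]: prevalences, penetrances, stage fractions,
#: uptake rates and intervention risk ratios.
PROBABILITY_FIELDS = (
    "p1", "p15", "p16", "p_BC_general", "p_OC_in_BRCAneg", "p_BC_in_BRCAneg",
    "ratio_early_OC", "ratio_early_BC",
    "p20", "p26", "p32", "p38",
    "rr_OC_RRA", "rr_BC_RRA", "rr_OC_RRM", "rr_BC_RRM",
    "rr_OC_RRSO", "rr_BC_RRSO", "rr_BC_RRM_RRSO",
    "p50", "p51",
)

UTILITY_FIELDS = (
    "u_early_OC", "u_early_BC", "u_late_OC", "u_late_BC", "u_healthy",
    "u_RRM_y1", "u_RRSO_y1",
)

SURVIVAL_FIELDS = (
    "s_early_OC", "s_early_BC", "s_late_OC", "s_late_BC", "s_healthy",
)

COST_FIELDS = (
    "cost_general_examination", "cost_periodical_examination",
    "cost_FH_consel", "cost_brca_test", "cost_rra", "cost_rrm",
    "cost_rrso", "cost_hrt", "cost_diagnosis_cancer",
)

#: reported 95% confidence intervals (absent entries vary by +/-10% / +/-30%)
_CONFIDENCE_INTERVALS: dict[str, tuple[float, float]] = {
    "p1": (0.002690, 0.005240),
    "p15": (0.069231, 0.166615),
    "p16": (0.333, 0.434),
    "p_OC_in_BRCAneg": (0.003, 0.007),
    "p20": (0.136, 0.19),
    "p26": (0.0815, 0.3015),
    "p32": (0.0415, 0.4915),
    "rr_OC_RRA": (0.41, 0.67),
    "rr_BC_RRA": (0.40, 1.03),
    "rr_BC_RRM": (0.041, 0.317),
    "rr_OC_RRSO": (0.12, 0.39),
    "rr_BC_RRSO": (0.37, 0.65),
    "rr_BC_RRM_RRSO": (0.01, 0.22),
    "p50": (0.0047, 0.0179),
    "s_early_OC": (0.379, 0.398),
    "s_early_BC": (0.736, 0.741),
    "s_late_OC": (0.163, 0.191),
    "s_late_BC": (0.599, 0.607),
}


@dataclass(frozen=True)
class ParameterSet:
    """Base-case parameter values for Chinese women aged 40-60.

    Penetrances (``p15``, ``p16``) are risks of developing ovarian / breast
    cancer by age 70 in BRCA1/2 carriers; survival proportions are 10-year
    survival conditional on the detected stage.
    """

    # prevalences and penetrances
    p1: float = 0.003965            # BRCA1/2 prevalence, general women
    p15: float = 0.130385           # OC risk by 70, carriers
    p16: float = 0.374              # BC risk by 70, carriers
    p_BC_general: float = 0.036     # BC risk, general women (consistency check only)
    p_OC_in_BRCAneg: float = 0.004
    p_BC_in_BRCAneg: float = 0.034654
    # stage mix among symptom-detected cancers
    ratio_early_OC: float = 0.30
    ratio_early_BC: float = 0.621
    # uptake of risk-reducing interventions among identified carriers
    p20: float = 0.163              # chemoprevention (RRA)
    p26: float = 0.2115             # RRM only
    p32: float = 0.2915             # RRSO only
    p38: float = 0.2585             # RRM and RRSO
    # intervention risk ratios
    rr_OC_RRA: float = 0.53
    rr_BC_RRA: float = 0.64
    rr_OC_RRM: float = 1.0
    rr_BC_RRM: float = 0.114
    rr_OC_RRSO: float = 0.21
    rr_BC_RRSO: float = 0.49
    rr_BC_RRM_RRSO: float = 0.05
    # family history
    p50: float = 0.0098             # FH+ prevalence, general population
    p51: float = 0.10               # BRCA1/2 prevalence among FH+
    # utilities
    u_early_OC: float = 0.81
    u_early_BC: float = 0.71
    u_late_OC: float = 0.55
    u_late_BC: float = 0.65
    u_healthy: float = 1.0
    u_RRM_y1: float = 0.88          # first-year utility after RRM
    u_RRSO_y1: float = 0.95         # first-year utility after RRSO
    # 10-year survival proportions
    s_early_OC: float = 0.388
    s_early_BC: float = 0.739
    s_late_OC: float = 0.176
    s_late_BC: float = 0.603
    s_healthy: float = 0.977658738
    # unit costs, yuan
    cost_general_examination: float = 400.0
    cost_periodical_examination: float = 1500.0
    cost_FH_consel: float = 80.0
    cost_brca_test: float = 3600.0
    cost_rra: float = 536.0
    cost_rrm: float = 5414.0
    cost_rrso: float = 26881.0
    cost_hrt: float = 4200.0
    cost_diagnosis_cancer: float = 1600.0
    # analysis settings
    horizon_years: float = 10.0
    wtp: float = 268200.0           # 3x GDP per capita, yuan/QALY
    fh_detection_convention: str = "coherent"  # or "paper_compat"

    def replace(self, **overrides: float | str) -> "ParameterSet":
        """Return a copy with the given fields overridden."""
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise ConfigError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def as_dict(self) -> dict[str, float | str]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class UncertainParameter:
    """Uncertainty specification for one parameter.

    ``family`` is the PSA sampling family (beta for probability-like
    quantities, gamma for costs, lognormal for utilities and survival);
    ``vary_rule`` governs the one-way DSA range (reported CI if available,
    otherwise +/-10%, +/-30% for costs).
    """

    name: str
    base: float
    ci_low: float | None = None
    ci_high: float | None = None
    family: str = "beta"            # beta | gamma | lognormal | fixed
    vary_rule: str = "ci"           # ci | pct10 | pct30

    def __post_init__(self) -> None:
        if self.ci_low is not None and not (self.ci_low <= self.base <= self.ci_high):
            raise ValueError(
                f"{self.name}: CI ({self.ci_low}, {self.ci_high}) does not bracket "
                f"base {self.base}"
            )


class ConfigError(ValueError):
    """Raised for malformed or incomplete configuration files."""


def default_parameters() -> ParameterSet:
    """The base-case parameter set (all reported point estimates)."""
    return ParameterSet()


def uncertain_parameters(params: ParameterSet | None = None) -> dict[str, UncertainParameter]:
    """Uncertainty specifications for the 42 varied model parameters.

    The roster is every probability, utility, survival and cost field;
    the horizon, the WTP threshold and the wiring convention are structural
    and never varied.
    """
    params = params or default_parameters()
    out: dict[str, UncertainParameter] = {}
    for name in PROBABILITY_FIELDS:
        ci = _CONFIDENCE_INTERVALS.get(name)
        out[name] = UncertainParameter(
            name, getattr(params, name),
            ci_low=ci[0] if ci else None, ci_high=ci[1] if ci else None,
            family="beta", vary_rule="ci" if ci else "pct10",
        )
    for name in UTILITY_FIELDS + SURVIVAL_FIELDS:
        ci = _CONFIDENCE_INTERVALS.get(name)
        out[name] = UncertainParameter(
            name, getattr(params, name),
            ci_low=ci[0] if ci else None, ci_high=ci[1] if ci else None,
            family="lognormal", vary_rule="ci" if ci else "pct10",
        )
    for name in COST_FIELDS:
        out[name] = UncertainParameter(
            name, getattr(params, name), family="gamma", vary_rule="pct30",
        )
    return out


def interval_for(param: UncertainParameter) -> tuple[float, float]:
    """One-way DSA range: the 95% CI if reported, else +/-10% (+/-30% costs).

    Bounded quantities (probabilities, utilities, survival) are clipped to
    [0, 1] so the range never leaves the parameter's support.
    """
    if param.ci_low is not None:
        low, high = param.ci_low, param.ci_high
    elif param.vary_rule == "pct30" or param.family == "gamma":
        low, high = param.base * 0.70, param.base * 1.30
    else:
        low, high = param.base * 0.90, param.base * 1.10
    if param.family in ("beta", "lognormal"):
        low, high = max(low, 0.0), min(high, 1.0) if param.base <= 1.0 else high
    return (min(low, param.base), max(high, param.base))


def validate(params: ParameterSet) -> list[str]:
    """Check structural invariants; returns a list of human-readable issues."""
    issues: list[str] = []
    for name in PROBABILITY_FIELDS + UTILITY_FIELDS + SURVIVAL_FIELDS:
        v = getattr(params, name)
        if not 0.0 <= v <= 1.0:
            issues.append(f"{name} = {v} outside [0, 1]")
    for name in COST_FIELDS:
        v = getattr(params, name)
        if v < 0:
            issues.append(f"negative cost: {name} = {v}")
    uptake = params.p20 + params.p26 + params.p32 + params.p38
    if uptake > 1.0 + 1e-12:
        issues.append(f"uptake sum > 1: p20+p26+p32+p38 = {uptake:.6g}")
    if params.horizon_years <= 0:
        issues.append(f"horizon_years = {params.horizon_years} must be > 0")
    if params.wtp <= 0:
        issues.append(f"wtp = {params.wtp} must be > 0")
    if params.fh_detection_convention not in ("coherent", "paper_compat"):
        issues.append(
            f"fh_detection_convention = {params.fh_detection_convention!r} "
            "not one of {'coherent', 'paper_compat'}"
        )
    if (params.fh_detection_convention == "coherent"
            and params.p50 * params.p51 > params.p1 + 1e-15):
        issues.append(
            "p50*p51 > p1: family-history carriers exceed total carrier "
            "prevalence (coherent mode)"
        )
    return issues


# ---------------------------------------------------------------------------
# configuration round-tripping (flat YAML key: value mapping)

_FIELD_NAMES = tuple(f.name for f in fields(ParameterSet))


def save_config(params: ParameterSet, path: str | Path) -> None:
    """Write a flat key: value config file covering every field."""
    data = {k: (v if isinstance(v, str) else float(v))
            for k, v in params.as_dict().items()}
    Path(path).write_text(
        yaml.safe_dump(data, sort_keys=False, default_flow_style=False)
    )


def load_config(path: str | Path) -> ParameterSet:
    """Load a flat config file; every field must be present, no extras."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a flat key: value mapping")
    unknown = sorted(set(raw) - set(_FIELD_NAMES))
    if unknown:
        raise ConfigError(f"{path}: unknown key(s): {unknown}")
    missing = sorted(set(_FIELD_NAMES) - set(raw))
    if missing:
        raise ConfigError(f"{path}: missing key(s): {missing}")
    values: dict[str, float | str] = {}
    for k, v in raw.items():
        if k == "fh_detection_convention":
            values[k] = str(v)
        else:
            try:
                values[k] = float(v)
            except (TypeError, ValueError):
                raise ConfigError(f"{path}: non-numeric value for {k}: {v!r}") from None
    return ParameterSet(**values)


def overrides_from_mapping(params: ParameterSet,
                           overrides: dict[str, float]) -> ParameterSet:
    """Apply a scenario-style override mapping and re-validate."""
    updated = params.replace(**overrides)
    issues = validate(updated)
    if issues:
        raise ConfigError("invalid overrides: " + "; ".join(issues))
    return updated


def iter_names(which: Iterable[str] | None = None) -> tuple[str, ...]:
    """Names of all varied parameters (helper for CLI rosters)."""
    return tuple(which) if which else tuple(uncertain_parameters())
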