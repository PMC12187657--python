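"""Synthetic instances for property testing, plus bundled fixtures.

Two generators back the test suite: ``random_parameter_set`` draws valid
parameter sets (jittered around base case, or broadly over plausible
ranges) so tree invariants can be checked far from the published values;
``random_tree`` builds small random chance trees whose expected cost and
QALY are computed *during generation* by an independent path summation,
giving an oracle for the evaluation engine.

``write_fixtures`` emits the base-case config, the bundled scenario
definitions and the varied-parameter roster as plain-text files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import params as params_mod
from .params import ParameterSet, default_parameters, save_config, validate
from .sensitivity import bundled_scenarios
from .tree import Branch, ChanceNode, DecisionTree, Leaf, Node

__all__ = [
    "SyntheticTreeInstance", "random_parameter_set", "random_tree",
    "write_fixtures",
]

# broad-mode sampling ranges chosen to stay structurally plausible:
# small prevalences stay small, uptakes are rescaled if they collide.
_BROAD_RANGES: dict[str, tuple[float, float]] = {
    "p1": (5e-4, 0.03), "p15": (0.02, 0.5), "p16": (0.05, 0.8),
    "p_BC_general": (0.005, 0.1), "p_OC_in_BRCAneg": (5e-4, 0.02),
    "p_BC_in_BRCAneg": (0.005, 0.1),
    "ratio_early_OC": (0.05, 0.95), "ratio_early_BC": (0.05, 0.95),
    "p20": (0.0, 0.5), "p26": (0.0, 0.5), "p32": (0.0, 0.5), "p38": (0.0, 0.5),
    "rr_OC_RRA": (0.05, 1.0), "rr_BC_RRA": (0.05, 1.0),
    "rr_OC_RRM": (0.05, 1.0), "rr_BC_RRM": (0.05, 1.0),
    "rr_OC_RRSO": (0.05, 1.0), "rr_BC_RRSO": (0.05, 1.0),
    "rr_BC_RRM_RRSO": (0.01, 1.0),
    "p50": (0.002, 0.1), "p51": (0.01, 0.5),
    "u_early_OC": (0.3, 1.0), "u_early_BC": (0.3, 1.0),
    "u_late_OC": (0.2, 1.0), "u_late_BC": (0.2, 1.0), "u_healthy": (0.8, 1.0),
    "u_RRM_y1": (0.5, 1.0), "u_RRSO_y1": (0.5, 1.0),
    "s_early_OC": (0.1, 0.9), "s_early_BC": (0.3, 0.95),
    "s_late_OC": (0.05, 0.6), "s_late_BC": (0.2, 0.9), "s_healthy": (0.85, 1.0),
}


def random_parameter_set(rng: np.random.Generator,
                         mode: str = "near_base",
                         jitter: float = 0.20) -> ParameterSet:
    """Draw a structurally valid :class:`ParameterSet`.

    ``near_base`` multiplies each varied value by U(1-jitter, 1+jitter)
    (clipped to the unit interval where bounded); ``broad`` samples uniformly
    over plausible ranges.  Uptake rates are rescaled when their sum exceeds
    1 and the family-history carrier mass is repaired to keep p50*p51 <= p1.
    """
    base = default_parameters()
    values: dict[str, float] = {}
    bounded = set(params_mod.PROBABILITY_FIELDS + params_mod.UTILITY_FIELDS
                  + params_mod.SURVIVAL_FIELDS)
    names = (params_mod.PROBABILITY_FIELDS + params_mod.UTILITY_FIELDS
             + params_mod.SURVIVAL_FIELDS + params_mod.COST_FIELDS)
    if mode == "near_base":
        for name in names:
            v = getattr(base, name) * rng.uniform(1.0 - jitter, 1.0 + jitter)
            if name in bounded:
                v = min(max(v, 0.0), 1.0)
            values[name] = v
    elif mode == "broad":
        for name in names:
            if name in _BROAD_RANGES:
                lo, hi = _BROAD_RANGES[name]
                values[name] = rng.uniform(lo, hi)
            else:  # costs
                values[name] = getattr(base, name) * rng.uniform(0.2, 3.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    uptake = values["p20"] + values["p26"] + values["p32"] + values["p38"]
    if uptake > 1.0:
        scale = 0.999 / uptake
        for k in ("p20", "p26", "p32", "p38"):
            values[k] *= scale
    if values["p50"] * values["p51"] > values["p1"]:
        # repair: shrink p51 below the feasibility boundary
        values["p51"] = values["p1"] / values["p50"] * rng.uniform(0.0, 1.0)
    out = base.replace(**values)
    issues = validate(out)
    if issues:  # pragma: no cover - generator contract
        raise AssertionError(f"generator produced invalid set: {issues}")
    return out


@dataclass(frozen=True)
class SyntheticTreeInstance:
    """A random chance tree with generator-side closed-form expectations."""

    tree: DecisionTree
    closed_form_cost: float
    closed_form_qaly: float
    n_paths: int


def _random_node(rng: np.random.Generator, depth: int, branching: int,
                 counter: list[int]) -> Node:
    if depth == 0 or (counter[0] > 1 and rng.random() < 0.3):
        counter[0] += 1
        return Leaf(state=str(rng.choice(["early_OC", "late_OC", "early_BC",
                                          "late_BC", "no_cancer"])),
                    cost=float(rng.uniform(0.0, 1e4)),
                    qaly=float(rng.uniform(0.0, 10.0)))
    k = int(rng.integers(2, branching + 1))
    probs = rng.dirichlet(np.ones(k))
    probs[-1] = 1.0 - probs[:-1].sum()  # exact unit sum
    branches = tuple(
        Branch(f"b{i}", float(probs[i]),
               _random_node(rng, depth - 1, branching, counter))
        for i in range(k)
    )
    counter[0] += 1
    return ChanceNode(f"n{counter[0]}", branches)


def _closed_form(node: Node) -> tuple[float, float, int]:
    """Independent iterative path summation (the oracle, not the engine)."""
    total_cost = total_qaly = 0.0
    n_paths = 0
    stack: list[tuple[Node, float]] = [(node, 1.0)]
    while stack:
        current, p = stack.pop()
        if isinstance(current, Leaf):
            total_cost += p * current.cost
            total_qaly += p * current.qaly
            n_paths += 1
        else:
            stack.extend((b.node, p * b.probability) for b in current.branches)
    return total_cost, total_qaly, n_paths


def random_tree(rng: np.random.Generator, depth: int = 4,
                branching: int = 4) -> SyntheticTreeInstance:
    """Random chance tree plus its generator-computed expectations."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    root = _random_node(rng, depth, branching, counter=[0])
    if isinstance(root, Leaf):  # ensure at least one chance node
        root = ChanceNode("root", (Branch("only", 1.0, root),))
    cost, qaly, n_paths = _closed_form(root)
    return SyntheticTreeInstance(DecisionTree("synthetic", root),
                                 cost, qaly, n_paths)


def write_fixtures(directory: str | Path) -> list[Path]:
    """Emit the base-case config, scenario specs, and the DSA roster."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    table1 = directory / "table1.yaml"
    save_config(default_parameters(), table1)
    written.append(table1)

    scenarios = directory / "scenarios.yaml"
    payload = {name: {"description": spec.description,
                      "overrides": spec.overrides}
               for name, spec in bundled_scenarios().items()}
    scenarios.write_text(yaml.safe_dump(payload, sort_keys=False))
    written.append(scenarios)

    roster = directory / "dsa_roster.txt"
    roster.write_text("\n".join(params_mod.uncertain_parameters()) + "\n")
    written.append(roster)
    return written
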