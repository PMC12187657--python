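"""Decision trees for the three screening strategies.

The model compares, over a 10-year horizon and from a payer perspective:

``symptom_only``
    no genetic testing; carriers and non-carriers are undetected and face
    their untreated cancer risks.
``population_based``
    every woman is BRCA1/2 tested; identified carriers distribute over five
    management arms (chemoprevention, RRM only, RRSO only, RRM+RRSO, and
    intensified surveillance for the residual).
``fh_based``
    family-history counselling first; only FH-positive women are tested, and
    identified carriers enter the same five arms.

Each root-to-leaf path ends in one of five mutually exclusive states
(early/late ovarian cancer, early/late breast cancer, no cancer) and carries
an accumulated cost and a QALY payoff, ``QALY = horizon x 10-year survival x
utility`` minus any first-year surgical disutility.

Two modelling conventions matter and are documented in docs/methods.md:
ovarian and breast cancer are mutually exclusive outcomes (breast-cancer
probability is clipped to the non-ovarian remainder), and cancers arising in
carriers under active management/surveillance are detected at an early stage,
whereas symptom-detected cancers follow the symptomatic stage mix
(``ratio_early_OC``/``ratio_early_BC``).

For the FH-based strategy two wirings of the detected-carrier mass are
available (``ParameterSet.fh_detection_convention``): ``coherent`` conserves
total carrier prevalence p1 and detects p50*p51 of the population, while
``paper_compat`` uses the p50*p51 mass for costs but a p1*p51 mass for the
QALY side, matching the published base-case QALY gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Union

from .params import ParameterSet, validate

__all__ = [
    "LEAF_STATES", "STRATEGIES", "CANCER_STATES",
    "Arm", "Leaf", "Branch", "ChanceNode", "DecisionTree", "PathOutcome",
    "StrategyResult", "TreeStructureError", "InvalidParametersError",
    "carrier_arms", "adjusted_risks", "leaf_qaly", "cancer_outcome_split",
    "build_strategy", "evaluate", "enumerate_paths", "evaluate_strategy",
]

LEAF_STATES = ("early_OC", "late_OC", "early_BC", "late_BC", "no_cancer")
CANCER_STATES = LEAF_STATES[:4]
STRATEGIES = ("symptom_only", "population_based", "fh_based")

_PROB_TOL = 1e-12


class TreeStructureError(ValueError):
    """A chance node's branch probabilities are invalid."""


class InvalidParametersError(ValueError):
    """The parameter set violates a structural precondition of the tree."""


@dataclass(frozen=True)
class Arm:
    """One management arm for an identified BRCA1/2 carrier."""

    label: str
    weight: float                # fraction of carriers entering this arm
    rr_OC: float                 # multiplicative effect on ovarian-cancer risk
    rr_BC: float                 # multiplicative effect on breast-cancer risk
    arm_cost: float              # one-off management cost, yuan
    arm_disutility_qaly: float   # first-year surgical disutility, QALYs
    detected: bool = True        # under surveillance: cancers caught early


@dataclass(frozen=True)
class Leaf:
    state: str
    cost: float
    qaly: float
    arm: str = "none"


@dataclass(frozen=True)
class Branch:
    label: str
    probability: float
    node: "Node"


@dataclass(frozen=True)
class ChanceNode:
    label: str
    branches: tuple[Branch, ...]


Node = Union[Leaf, ChanceNode]


@dataclass(frozen=True)
class PathOutcome:
    probability: float
    cost: float
    qaly: float
    leaf: str
    arm: str
    labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class StrategyResult:
    strategy: str
    expected_cost: float
    expected_qaly: float
    leaf_probabilities: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class DecisionTree:
    """Strategy tree; ``qaly_root`` (paper_compat FH wiring only) carries an
    alternative probability wiring used for the QALY expectation."""

    strategy: str
    root: Node
    qaly_root: Node | None = None


# ---------------------------------------------------------------------------
# building blocks

def carrier_arms(params: ParameterSet) -> list[Arm]:
    """The five management arms with Table-1 uptake weights.

    The surveillance arm takes the residual weight; RRSO-containing arms
    include hormone replacement therapy; surveillance cost (periodic
    examination) attaches only to the surveillance-only arm.
    """
    residual = 1.0 - params.p20 - params.p26 - params.p32 - params.p38
    if residual < -1e-12:
        raise InvalidParametersError(
            f"carrier uptake rates sum to {1 - residual:.6g} > 1"
        )
    dis_rrm = (1.0 - params.u_RRM_y1) * 1.0
    dis_rrso = (1.0 - params.u_RRSO_y1) * 1.0
    return [
        Arm("RRA", params.p20, params.rr_OC_RRA, params.rr_BC_RRA,
            params.cost_rra, 0.0),
        Arm("RRM_only", params.p26, params.rr_OC_RRM, params.rr_BC_RRM,
            params.cost_rrm, dis_rrm),
        Arm("RRSO_only", params.p32, params.rr_OC_RRSO, params.rr_BC_RRSO,
            params.cost_rrso + params.cost_hrt, dis_rrso),
        Arm("RRM_and_RRSO", params.p38, params.rr_OC_RRSO, params.rr_BC_RRM_RRSO,
            params.cost_rrm + params.cost_rrso + params.cost_hrt,
            dis_rrm + dis_rrso),
        Arm("surveillance_only", max(residual, 0.0), 1.0, 1.0,
            params.cost_periodical_examination, 0.0),
    ]


def adjusted_risks(arm: Arm, params: ParameterSet) -> tuple[float, float]:
    """Carrier cancer risks under an arm: penetrance x arm risk ratio."""
    return (min(params.p15 * arm.rr_OC, 1.0), min(params.p16 * arm.rr_BC, 1.0))


def leaf_qaly(leaf: str, params: ParameterSet) -> float:
    """QALY payoff of a terminal state: horizon x 10y survival x utility."""
    s = {
        "early_OC": params.s_early_OC, "late_OC": params.s_late_OC,
        "early_BC": params.s_early_BC, "late_BC": params.s_late_BC,
        "no_cancer": params.s_healthy,
    }[leaf]
    u = {
        "early_OC": params.u_early_OC, "late_OC": params.u_late_OC,
        "early_BC": params.u_early_BC, "late_BC": params.u_late_BC,
        "no_cancer": params.u_healthy,
    }[leaf]
    return params.horizon_years * s * u


def cancer_outcome_split(risk_OC: float, risk_BC: float,
                         params: ParameterSet, *,
                         detected: bool = False) -> dict[str, float]:
    """Distribute one person over the five terminal states.

    Ovarian and breast cancer are mutually exclusive (no double primaries):
    P(OC) = risk_OC and P(BC) = min(risk_BC, 1 - risk_OC).  Symptom-detected
    cancers split early/late by the ``ratio_early_*`` stage mix; cancers in
    carriers under active management (``detected=True``) are caught early.
    """
    if not (0.0 <= risk_OC <= 1.0 and 0.0 <= risk_BC <= 1.0):
        raise InvalidParametersError(
            f"risks outside [0,1]: ({risk_OC}, {risk_BC})"
        )
    p_bc = min(risk_BC, 1.0 - risk_OC)
    r_oc = 1.0 if detected else params.ratio_early_OC
    r_bc = 1.0 if detected else params.ratio_early_BC
    return {
        "early_OC": risk_OC * r_oc,
        "late_OC": risk_OC * (1.0 - r_oc),
        "early_BC": p_bc * r_bc,
        "late_BC": p_bc * (1.0 - r_bc),
        "no_cancer": 1.0 - risk_OC - p_bc,
    }


# ---------------------------------------------------------------------------
# tree construction

def _outcome_node(label: str, risk_OC: float, risk_BC: float,
                  params: ParameterSet, base_cost: float,
                  disutility: float, arm: str, detected: bool) -> ChanceNode:
    split = cancer_outcome_split(risk_OC, risk_BC, params, detected=detected)
    branches = []
    for state, p in split.items():
        cost = base_cost + (params.cost_diagnosis_cancer
                            if state != "no_cancer" else 0.0)
        branches.append(Branch(
            state, p, Leaf(state, cost, leaf_qaly(state, params) - disutility,
                           arm=arm)))
    return ChanceNode(label, tuple(branches))


def _carrier_management_node(params: ParameterSet, base_cost: float,
                             label: str) -> ChanceNode:
    branches = []
    for arm in carrier_arms(params):
        r_oc, r_bc = adjusted_risks(arm, params)
        branches.append(Branch(
            arm.label, arm.weight,
            _outcome_node(f"{label}/{arm.label}", r_oc, r_bc, params,
                          base_cost + arm.arm_cost, arm.arm_disutility_qaly,
                          arm.label, arm.detected)))
    return ChanceNode(label, tuple(branches))


def _fh_root(params: ParameterSet, carrier_rate_fhpos: float,
             carrier_rate_fhneg: float) -> ChanceNode:
    base = params.cost_general_examination + params.cost_FH_consel
    tested = base + params.cost_brca_test
    fh_pos = ChanceNode("FH_pos", (
        Branch("BRCA_pos", carrier_rate_fhpos,
               _carrier_management_node(params, tested, "FH_pos/BRCA_pos")),
        Branch("BRCA_neg", 1.0 - carrier_rate_fhpos,
               _outcome_node("FH_pos/BRCA_neg", params.p_OC_in_BRCAneg,
                             params.p_BC_in_BRCAneg, params, tested,
                             0.0, "none", False)),
    ))
    fh_neg = ChanceNode("FH_neg", (
        Branch("BRCA_pos_undetected", carrier_rate_fhneg,
               _outcome_node("FH_neg/BRCA_pos", params.p15, params.p16,
                             params, base, 0.0, "none", False)),
        Branch("BRCA_neg", 1.0 - carrier_rate_fhneg,
               _outcome_node("FH_neg/BRCA_neg", params.p_OC_in_BRCAneg,
                             params.p_BC_in_BRCAneg, params, base,
                             0.0, "none", False)),
    ))
    return ChanceNode("root", (
        Branch("FH_pos", params.p50, fh_pos),
        Branch("FH_neg", 1.0 - params.p50, fh_neg),
    ))


def build_strategy(strategy: str, params: ParameterSet) -> DecisionTree:
    """Construct the decision tree for one strategy."""
    issues = validate(params)
    if issues:
        raise InvalidParametersError("; ".join(issues))
    if strategy == "symptom_only":
        base = params.cost_general_examination
        root = ChanceNode("root", (
            Branch("BRCA_pos_undetected", params.p1,
                   _outcome_node("BRCA_pos", params.p15, params.p16, params,
                                 base, 0.0, "none", False)),
            Branch("BRCA_neg", 1.0 - params.p1,
                   _outcome_node("BRCA_neg", params.p_OC_in_BRCAneg,
                                 params.p_BC_in_BRCAneg, params, base,
                                 0.0, "none", False)),
        ))
        return DecisionTree(strategy, root)
    if strategy == "population_based":
        base = params.cost_general_examination + params.cost_brca_test
        root = ChanceNode("root", (
            Branch("BRCA_pos", params.p1,
                   _carrier_management_node(params, base, "BRCA_pos")),
            Branch("BRCA_neg", 1.0 - params.p1,
                   _outcome_node("BRCA_neg", params.p_OC_in_BRCAneg,
                                 params.p_BC_in_BRCAneg, params, base,
                                 0.0, "none", False)),
        ))
        return DecisionTree(strategy, root)
    if strategy == "fh_based":
        detected = params.p50 * params.p51
        fh_neg_mass = 1.0 - params.p50
        if params.fh_detection_convention == "coherent":
            if detected > params.p1 + 1e-15:
                raise InvalidParametersError(
                    "p50*p51 > p1: negative FH-negative carrier frequency"
                )
            fh_neg_rate = ((params.p1 - detected) / fh_neg_mass
                           if fh_neg_mass > 0.0 else 0.0)
            return DecisionTree(strategy, _fh_root(params, params.p51, fh_neg_rate))
        # paper_compat: costs follow the p50*p51 detected mass, QALYs a
        # p1*p51 detected mass (both conserve total carrier prevalence).
        if params.p50 <= 0.0:
            raise InvalidParametersError("paper_compat fh_based requires p50 > 0")
        fh_neg_rate = ((params.p1 - detected) / fh_neg_mass
                       if fh_neg_mass > 0.0 else 0.0)
        cost_root = _fh_root(params, params.p51, max(fh_neg_rate, 0.0))
        q_rate = min(params.p1 * params.p51 / params.p50, 1.0)
        q_neg_rate = (params.p1 * (1.0 - params.p51) / fh_neg_mass
                      if fh_neg_mass > 0.0 else 0.0)
        qaly_root = _fh_root(params, q_rate, q_neg_rate)
        return DecisionTree(strategy, cost_root, qaly_root=qaly_root)
    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# evaluation

def _check_node(node: ChanceNode) -> None:
    total = 0.0
    for b in node.branches:
        if not -_PROB_TOL <= b.probability <= 1.0 + _PROB_TOL:
            raise TreeStructureError(
                f"node {node.label!r}: branch {b.label!r} probability "
                f"{b.probability} outside [0, 1]"
            )
        total += b.probability
    if abs(total - 1.0) > 1e-9:
        raise TreeStructureError(
            f"node {node.label!r}: branch probabilities sum to {total!r}"
        )


def _expect(node: Node) -> tuple[float, float, dict[str, float]]:
    """Recursive expectation: (cost, qaly, leaf-state mass)."""
    if isinstance(node, Leaf):
        return node.cost, node.qaly, {node.state: 1.0}
    _check_node(node)
    cost = qaly = 0.0
    mass: dict[str, float] = {}
    for b in node.branches:
        c, q, m = _expect(b.node)
        cost += b.probability * c
        qaly += b.probability * q
        for k, v in m.items():
            mass[k] = mass.get(k, 0.0) + b.probability * v
    return cost, qaly, mass


def _walk(node: Node, p: float, labels: tuple[str, ...]) -> Iterator[PathOutcome]:
    if isinstance(node, Leaf):
        yield PathOutcome(p, node.cost, node.qaly, node.state, node.arm, labels)
        return
    _check_node(node)
    for b in node.branches:
        yield from _walk(b.node, p * b.probability, labels + (b.label,))


def enumerate_paths(tree: DecisionTree, which: str = "cost") -> list[PathOutcome]:
    """Flat enumeration of all root-to-leaf paths.

    ``which`` selects the probability wiring ("cost" or "qaly"); the two
    differ only for the FH-based strategy under the paper_compat convention.
    """
    root = tree.root if which == "cost" or tree.qaly_root is None else tree.qaly_root
    return list(_walk(root, 1.0, ()))


def evaluate(tree: DecisionTree) -> StrategyResult:
    """Expected cost and QALY by recursive expectation over the tree."""
    cost, qaly, mass = _expect(tree.root)
    if tree.qaly_root is not None:
        _, qaly, _ = _expect(tree.qaly_root)
    leaf_probs = {state: mass.get(state, 0.0) for state in LEAF_STATES}
    return StrategyResult(tree.strategy, cost, qaly, leaf_probs)


def evaluate_strategy(strategy: str, params: ParameterSet) -> StrategyResult:
    """Build and evaluate one strategy in a single call."""
    return evaluate(build_strategy(strategy, params))


def evaluate_all(params: ParameterSet) -> dict[str, StrategyResult]:
    """Evaluate the three strategies at one parameter set."""
    return {s: evaluate_strategy(s, params) for s in STRATEGIES}
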