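"""Incremental cost-effectiveness statistics.

ICER = (cost_A - cost_B) / (QALY_A - QALY_B), in yuan per QALY gained; a
strategy is cost-effective when its ICER against the comparator does not
exceed the willingness-to-pay threshold (3x GDP per capita, 268,200
yuan/QALY).  Net monetary benefit, NMB = QALY x WTP - cost, gives the
equivalent ranking criterion: NMB(A) > NMB(B) exactly when WTP exceeds the
pairwise ICER (for a QALY-gaining comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .tree import StrategyResult

__all__ = ["IncrementalResult", "icer", "nmb", "rank_at_wtp", "DAYS_PER_YEAR"]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise comparison of ``comparator`` against ``reference``."""

    delta_cost: float
    delta_qaly: float
    icer: float                 # signed; +/-inf sentinel when delta_qaly == 0
    classification: str         # cost_effective | not_cost_effective | dominant | dominated
    qaly_gain_days: float
    wtp: float


def icer(reference: StrategyResult, comparator: StrategyResult,
         wtp: float) -> IncrementalResult:
    """Incremental statistics for ``comparator`` vs ``reference``.

    Dominant: cheaper and more effective.  Dominated: costlier and less
    effective.  With equal QALYs the ICER is a signed infinity sentinel and
    classification follows the cost sign alone.
    """
    d_cost = comparator.expected_cost - reference.expected_cost
    d_qaly = comparator.expected_qaly - reference.expected_qaly
    if d_qaly == 0.0:
        ratio = math.copysign(math.inf, d_cost) if d_cost != 0.0 else 0.0
        cls = "cost_effective" if d_cost <= 0.0 else "not_cost_effective"
    else:
        ratio = d_cost / d_qaly
        if d_cost < 0.0 and d_qaly > 0.0:
            cls = "dominant"
        elif d_cost > 0.0 and d_qaly < 0.0:
            cls = "dominated"
        elif d_qaly > 0.0:
            cls = "cost_effective" if ratio <= wtp else "not_cost_effective"
        else:
            # less effective and cheaper: cost-effective only if the savings
            # per QALY forgone exceed the threshold
            cls = "cost_effective" if ratio > wtp else "not_cost_effective"
    return IncrementalResult(d_cost, d_qaly, ratio, cls,
                             d_qaly * DAYS_PER_YEAR, wtp)


def nmb(result: StrategyResult, wtp: float) -> float:
    """Net monetary benefit: QALY x WTP - cost."""
    return result.expected_qaly * wtp - result.expected_cost


def rank_at_wtp(results: list[StrategyResult], wtp: float) -> list[str]:
    """Strategy names in descending NMB order (ties -> lower cost first)."""
    if len(results) < 2:
        raise ValueError("need at least two strategies to rank")
    return [r.strategy for r in
            sorted(results, key=lambda r: (-nmb(r, wtp), r.expected_cost))]
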