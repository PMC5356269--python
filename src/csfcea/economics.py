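"""Strategy aggregation, incremental cost-effectiveness, and the challenge region.

Two strategies are compared: *do nothing* (no biomarker test; every patient
follows the undiagnosed trajectory for their true disease state) and
*biomarker analysis* (every patient takes the CSF test, pays its cost, incurs
the one-time lumbar-puncture QALY toll, and follows the trajectory of their
diagnostic outcome). The challenge region generalizes the comparison to a
hypothetical test with arbitrary sensitivity/specificity via the incremental
net monetary benefit identity, which is linear in both test characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cohort import DiagnosticOutcomeProbs
from .markov import LifetimeOutcome

__all__ = [
    "StrategyResult",
    "IncrementalResult",
    "ChallengeRegionSpec",
    "aggregate_strategy",
    "do_nothing_probs",
    "compare_strategies",
    "net_monetary_benefit",
    "inmb_test_comparison",
    "challenge_region",
]


@dataclass
class StrategyResult:
    """Probability-weighted lifetime totals for one diagnostic strategy."""

    label: str  # "do_nothing" or "biomarker"
    total_cost: float
    total_qalys: float
    breakdown: dict = field(default_factory=dict)  # outcome -> (prob, LifetimeOutcome)


@dataclass
class IncrementalResult:
    """Pairwise comparison of a new strategy against a reference."""

    delta_cost: float
    delta_qalys: float
    classification: str  # dominant | dominated | tradeoff
    icer: float | None  # defined only for the tradeoff quadrants


def aggregate_strategy(probs: DiagnosticOutcomeProbs,
                       outcomes: Mapping[str, LifetimeOutcome],
                       test_cost: float = 0.0, test_toll: float = 0.0,
                       tested: bool = True,
                       label: str = "biomarker") -> StrategyResult:
    """Probability-weight per-outcome lifetime values into a strategy total.

    For a tested strategy the test cost is added to the expected cost and the
    one-time QALY toll (incurred by every tested patient) subtracted from the
    expected QALYs. For the untested (do-nothing) strategy, pass the outcome
    probabilities from :func:`do_nothing_probs` and ``tested=False``.
    """
    weights = probs.as_dict()
    missing = [k for k in weights if k not in outcomes]
    if missing:
        raise KeyError(f"missing lifetime outcomes for {missing}")
    cost = sum(w * outcomes[k].discounted_cost for k, w in weights.items())
    qalys = sum(w * outcomes[k].discounted_qalys for k, w in weights.items())
    if tested:
        cost += test_cost
        qalys -= test_toll
    bd = {k: (w, outcomes[k]) for k, w in weights.items()}
    return StrategyResult(label=label, total_cost=cost, total_qalys=qalys, breakdown=bd)


def do_nothing_probs(probs: DiagnosticOutcomeProbs) -> DiagnosticOutcomeProbs:
    """Outcome mix without testing: all diseased patients remain undiagnosed
    (false-negative trajectory), all non-diseased remain untreated
    (true-negative trajectory)."""
    return DiagnosticOutcomeProbs(
        p_tp=0.0, p_fn=probs.p_tp + probs.p_fn,
        p_fp=0.0, p_tn=probs.p_fp + probs.p_tn)


def compare_strategies(new: StrategyResult, ref: StrategyResult) -> IncrementalResult:
    """Classify the incremental comparison and compute the ICER when defined.

    The ICER (incremental cost per QALY gained) is reported only in the
    trade-off quadrants (more costly and more effective, or the mirror);
    dominance is reported as a classification instead of a ratio.
    """
    dc = new.total_cost - ref.total_cost
    dq = new.total_qalys - ref.total_qalys
    if dq == 0.0:
        cls = "dominant" if dc < 0 else ("dominated" if dc > 0 else "tradeoff")
        return IncrementalResult(dc, dq, cls, None if dc else 0.0)
    if dc <= 0 and dq > 0:
        return IncrementalResult(dc, dq, "dominant", None)
    if dc >= 0 and dq < 0:
        return IncrementalResult(dc, dq, "dominated", None)
    return IncrementalResult(dc, dq, "tradeoff", dc / dq)


def net_monetary_benefit(s: StrategyResult, wtp: float) -> float:
    """NMB = willingness-to-pay x QALYs - cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * s.total_qalys - s.total_cost


@dataclass
class ChallengeRegionSpec:
    """Inputs of the test-comparison INMB identity.

    ``q1``/``q2`` are the comparator's sensitivity/specificity (0 and 1 for a
    no-test comparator: nobody is diagnosed); the per-outcome lifetime values
    come from the cohort model, and the test deltas are the new test's cost
    and short-term QALY toll relative to the comparator.
    """

    prevalence: float
    wtp: float
    q1: float
    q2: float
    qaly_tp: float
    qaly_fn: float
    qaly_fp: float
    qaly_tn: float
    cost_tp: float
    cost_fn: float
    cost_fp: float
    cost_tn: float
    delta_test_cost: float = 0.0
    delta_test_qaly: float = 0.0

    @classmethod
    def from_outcomes(cls, outcomes: Mapping[str, LifetimeOutcome], *,
                      prevalence: float, wtp: float,
                      q1: float = 0.0, q2: float = 1.0,
                      delta_test_cost: float = 0.0,
                      delta_test_qaly: float = 0.0) -> "ChallengeRegionSpec":
        return cls(
            prevalence=prevalence, wtp=wtp, q1=q1, q2=q2,
            qaly_tp=outcomes["TP"].discounted_qalys,
            qaly_fn=outcomes["FN"].discounted_qalys,
            qaly_fp=outcomes["FP"].discounted_qalys,
            qaly_tn=outcomes["TN"].discounted_qalys,
            cost_tp=outcomes["TP"].discounted_cost,
            cost_fn=outcomes["FN"].discounted_cost,
            cost_fp=outcomes["FP"].discounted_cost,
            cost_tn=outcomes["TN"].discounted_cost,
            delta_test_cost=delta_test_cost, delta_test_qaly=delta_test_qaly)

    @property
    def fn_prevention_value(self) -> float:
        """INMB of preventing one false-negative diagnosis."""
        return (self.wtp * (self.qaly_tp - self.qaly_fn)
                - (self.cost_tp - self.cost_fn))

    @property
    def fp_prevention_value(self) -> float:
        """INMB of preventing one false-positive diagnosis."""
        return (self.wtp * (self.qaly_tn - self.qaly_fp)
                - (self.cost_tn - self.cost_fp))


def inmb_test_comparison(spec: ChallengeRegionSpec, r1: float, r2: float) -> float:
    """Incremental net monetary benefit of a test with sensitivity ``r1`` and
    specificity ``r2`` against the comparator in ``spec``.

    Three terms: extra true-positives valued at the benefit of preventing a
    false negative, extra true-negatives valued at the benefit of preventing
    a false positive, minus the incremental test cost and monetized toll.
    """
    if not (0.0 <= r1 <= 1.0 and 0.0 <= r2 <= 1.0):
        raise ValueError("test characteristics must be in [0, 1]")
    p = spec.prevalence
    return (p * (r1 - spec.q1) * spec.fn_prevention_value
            + (1.0 - p) * (r2 - spec.q2) * spec.fp_prevention_value
            - spec.delta_test_cost - spec.wtp * spec.delta_test_qaly)


def challenge_region(spec: ChallengeRegionSpec, grid_step: float = 0.01):
    """Admissible (sensitivity, specificity) set with positive INMB.

    Returns ``(r1_grid, r2_grid, inmb, boundary)`` where ``inmb`` is evaluated
    on the full [0,1]^2 grid and ``boundary`` is the analytic INMB = 0 line
    expressed as specificity as a function of sensitivity (the identity is
    linear in both coordinates, so the boundary is a straight line).
    """
    if not (0.0 < grid_step <= 0.1):
        raise ValueError("grid_step must be in (0, 0.1]")
    r1 = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    r2 = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    g1, g2 = np.meshgrid(r1, r2, indexing="ij")
    p = spec.prevalence
    a = p * spec.fn_prevention_value
    b = (1.0 - p) * spec.fp_prevention_value
    const = (-p * spec.q1 * spec.fn_prevention_value
             - (1.0 - p) * spec.q2 * spec.fp_prevention_value
             - spec.delta_test_cost - spec.wtp * spec.delta_test_qaly)
    inmb = a * g1 + b * g2 + const

    if b != 0.0:
        boundary = [(x, (-const - a * x) / b) for x in r1]
    else:
        boundary = []
    return r1, r2, inmb, boundary
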