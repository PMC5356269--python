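"""Deterministic and probabilistic sensitivity analysis.

One-way analyses re-run the full pipeline at a parameter's published low and
high values; two-way analyses classify a grid of parameter pairs by
cost-effectiveness category; the prevalence-threshold search exploits the
fact that the lifetime outcomes per diagnostic group do not depend on the
pretest prevalence, so the incremental comparison is closed-form in the
prevalence once the four cohorts have been run. The probabilistic analysis
draws full parameter sets, re-runs the pipeline per draw, and summarizes the
joint distribution of incremental cost and effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .cohort import Accuracy, outcome_probabilities
from .economics import (IncrementalResult, StrategyResult, aggregate_strategy,
                        compare_strategies, do_nothing_probs)
from .markov import LifetimeOutcome, ScenarioFlags, run_all_groups
from .parameters import ParameterSet, get_param
from .sampling import sample_parameter_set

__all__ = [
    "PipelineResult",
    "run_pipeline",
    "incremental_at_prevalence",
    "DSAResult",
    "one_way_dsa",
    "TwoWayGrid",
    "two_way_dsa",
    "prevalence_threshold",
    "cost_saving_threshold",
    "run_scenario",
    "PSAResult",
    "run_psa",
]


@dataclass
class PipelineResult:
    """Everything the base-case analysis produces for one parameter set."""

    outcomes: dict[str, LifetimeOutcome]
    probs: object
    do_nothing: StrategyResult
    biomarker: StrategyResult
    incremental: IncrementalResult


def _accuracy(ps: ParameterSet) -> Accuracy:
    acc = ps.accuracy.bm_given_mr_negative
    return Accuracy(sn=acc.sn.value, sp=acc.sp.value)


def run_pipeline(ps: ParameterSet,
                 flags: ScenarioFlags | None = None) -> PipelineResult:
    """Run the four cohorts and aggregate both strategies at the configured
    pretest prevalence."""
    outcomes = run_all_groups(ps, flags)
    probs = outcome_probabilities(ps.cohort.pretest_prevalence.value, _accuracy(ps))
    dn = aggregate_strategy(do_nothing_probs(probs), outcomes, tested=False,
                            label="do_nothing")
    bm = aggregate_strategy(probs, outcomes,
                            test_cost=ps.costs.biomarker_test.value,
                            test_toll=ps.utilities.lumbar_puncture_toll.value,
                            tested=True, label="biomarker")
    return PipelineResult(outcomes, probs, dn, bm, compare_strategies(bm, dn))


def incremental_at_prevalence(prevalence: float, outcomes: dict[str, LifetimeOutcome],
                              ps: ParameterSet) -> IncrementalResult:
    """Incremental comparison at an arbitrary pretest prevalence, reusing
    already-computed lifetime outcomes (they are prevalence-independent)."""
    probs = outcome_probabilities(prevalence, _accuracy(ps))
    dn = aggregate_strategy(do_nothing_probs(probs), outcomes, tested=False,
                            label="do_nothing")
    bm = aggregate_strategy(probs, outcomes,
                            test_cost=ps.costs.biomarker_test.value,
                            test_toll=ps.utilities.lumbar_puncture_toll.value,
                            tested=True, label="biomarker")
    return compare_strategies(bm, dn)


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis

@dataclass
class DSAResult:
    param_id: str
    low_input: float
    high_input: float
    base_incremental: IncrementalResult
    low_incremental: IncrementalResult
    high_incremental: IncrementalResult

    @property
    def icer_range_width(self) -> float:
        """Width of the ICER swing, used for tornado ordering; dominance ends
        are treated as unbounded swings."""
        vals = []
        for inc in (self.low_incremental, self.high_incremental):
            vals.append(math.inf if inc.icer is None else inc.icer)
        base = (self.base_incremental.icer
                if self.base_incremental.icer is not None else 0.0)
        return max(abs(v - base) for v in vals)


def _with_value(ps: ParameterSet, path: str, value: float) -> ParameterSet:
    out = ps.copy()
    get_param(out, path).value = value
    return out


def one_way_dsa(param_id: str, ps: ParameterSet,
                flags: ScenarioFlags | None = None) -> DSAResult:
    """Re-run the full pipeline at a parameter's low and high values."""
    pv = get_param(ps, param_id)
    base = run_pipeline(ps, flags).incremental
    lo = run_pipeline(_with_value(ps, param_id, pv.low), flags).incremental
    hi = run_pipeline(_with_value(ps, param_id, pv.high), flags).incremental
    return DSAResult(param_id, pv.low, pv.high, base, lo, hi)


_CATEGORIES = ("cost_saving", "icer_le_50k", "icer_50_100k", "icer_gt_100k", "dominated")


def classify_incremental(inc: IncrementalResult,
                         low_wtp: float = 50_000.0,
                         high_wtp: float = 100_000.0) -> str:
    """Map an incremental result onto the standard display categories."""
    if inc.classification == "dominant":
        return "cost_saving"
    if inc.classification == "dominated":
        return "dominated"
    icer = inc.icer
    if inc.delta_qalys < 0:  # cheaper and worse: ICER is a forgone-savings rate
        return "dominated" if icer is not None and icer < high_wtp else "icer_gt_100k"
    if inc.delta_cost <= 0:
        return "cost_saving"
    if icer <= low_wtp:
        return "icer_le_50k"
    if icer <= high_wtp:
        return "icer_50_100k"
    return "icer_gt_100k"


@dataclass
class TwoWayGrid:
    param1: str
    param2: str
    values1: np.ndarray
    values2: np.ndarray
    classification: np.ndarray  # (len(values1), len(values2)) of category strings


def two_way_dsa(param1: str, values1, param2: str, values2,
                ps: ParameterSet, flags: ScenarioFlags | None = None) -> TwoWayGrid:
    """Classify the cost-effectiveness category over a grid of two parameters."""
    values1 = np.asarray(values1, dtype=float)
    values2 = np.asarray(values2, dtype=float)
    cls = np.empty((values1.size, values2.size), dtype=object)
    for i, v1 in enumerate(values1):
        ps1 = _with_value(ps, param1, float(v1))
        for j, v2 in enumerate(values2):
            res = run_pipeline(_with_value(ps1, param2, float(v2)), flags)
            cls[i, j] = classify_incremental(res.incremental)
    return TwoWayGrid(param1, param2, values1, values2, cls)


# ---------------------------------------------------------------------------
# prevalence thresholds

def _icer_of_p(p: float, outcomes, ps) -> float:
    inc = incremental_at_prevalence(p, outcomes, ps)
    if inc.icer is not None:
        return inc.icer
    # dominant comparisons sit below any positive willingness-to-pay;
    # dominated ones above
    return -math.inf if inc.classification == "dominant" else math.inf


def prevalence_threshold(wtp: float, ps: ParameterSet,
                         flags: ScenarioFlags | None = None,
                         bracket: tuple[float, float] = (0.005, 0.6),
                         tol: float = 1e-4) -> float:
    """Pretest prevalence at which the ICER equals the willingness-to-pay.

    The ICER is verified to be decreasing in prevalence over the bracket
    before root finding; if the ICER never crosses the threshold inside the
    bracket, the boundary behaviour is reported via ValueError.
    """
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be > 0")
    outcomes = run_all_groups(ps, flags)

    def g(p):
        inc = incremental_at_prevalence(p, outcomes, ps)
        # root of lambda*dQ - dC = 0 is numerically benign even near dQ = 0
        return wtp * inc.delta_qalys - inc.delta_cost

    lo, hi = bracket
    probe = np.linspace(lo, hi, 13)
    icers = [_icer_of_p(p, outcomes, ps) for p in probe]
    finite = [v for v in icers if math.isfinite(v)]
    if any(b > a for a, b in zip(finite, finite[1:])):
        raise ValueError("ICER is not monotone decreasing over the bracket")
    if g(lo) * g(hi) > 0:
        side = "below" if g(lo) > 0 else "above"
        raise ValueError(f"no threshold in bracket: ICER stays {side} "
                         f"the willingness-to-pay over {bracket}")
    return float(brentq(g, lo, hi, xtol=tol))


def cost_saving_threshold(ps: ParameterSet,
                          flags: ScenarioFlags | None = None,
                          bracket: tuple[float, float] = (0.005, 0.6)) -> float:
    """Pretest prevalence above which the biomarker strategy saves money."""
    outcomes = run_all_groups(ps, flags)

    def dc(p):
        return incremental_at_prevalence(p, outcomes, ps).delta_cost

    lo, hi = bracket
    if dc(lo) * dc(hi) > 0:
        raise ValueError("incremental cost does not change sign over the bracket")
    return float(brentq(dc, lo, hi, xtol=1e-4))


def run_scenario(flags: ScenarioFlags, ps: ParameterSet,
                 fp_benefit_fraction: float | None = None) -> IncrementalResult:
    """Full pipeline under a structural scenario.

    ``fp_benefit_fraction`` overrides the treatment-benefit share received by
    falsely diagnosed patients (its base value is 0).
    """
    work = ps
    if fp_benefit_fraction is not None:
        work = ps.copy()
        work.treatment.fp_benefit_fraction.value = fp_benefit_fraction
    return run_pipeline(work, flags).incremental


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

@dataclass
class PSAResult:
    """Summary of the probabilistic analysis: quadrant shares on the
    cost-effectiveness plane, acceptability probabilities, and empirical
    95% intervals."""

    draws: int
    seed: int
    quadrants: dict[str, float]
    ceac: dict[float, float]
    intervals: dict[str, tuple[float, float]]
    delta_costs: np.ndarray = field(repr=False)
    delta_qalys: np.ndarray = field(repr=False)
    redraws: int = 0


def run_psa(n: int, seed: int, wtp_list, ps: ParameterSet,
            flags: ScenarioFlags | None = None) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n`` independent draws.

    Fully reproducible from the seed: one random generator drives all draws,
    and parameters are sampled in a fixed order within each draw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dc = np.empty(n)
    dq = np.empty(n)
    dn_c = np.empty(n)
    dn_q = np.empty(n)
    bm_c = np.empty(n)
    bm_q = np.empty(n)
    for i in range(n):
        draw = sample_parameter_set(ps, rng)
        res = run_pipeline(draw, flags)
        dc[i] = res.incremental.delta_cost
        dq[i] = res.incremental.delta_qalys
        dn_c[i], dn_q[i] = res.do_nothing.total_cost, res.do_nothing.total_qalys
        bm_c[i], bm_q[i] = res.biomarker.total_cost, res.biomarker.total_qalys

    quadrants = {
        "cheaper_better": float(np.mean((dc < 0) & (dq > 0))),
        "costlier_better": float(np.mean((dc >= 0) & (dq > 0))),
        "cheaper_worse": float(np.mean((dc < 0) & (dq <= 0))),
        "costlier_worse": float(np.mean((dc >= 0) & (dq <= 0))),
    }
    ceac = {float(w): float(np.mean(w * dq - dc > 0)) for w in wtp_list}

    def ci(x):
        return (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))

    intervals = {
        "do_nothing_cost": ci(dn_c), "do_nothing_qalys": ci(dn_q),
        "biomarker_cost": ci(bm_c), "biomarker_qalys": ci(bm_q),
        "delta_cost": ci(dc), "delta_qalys": ci(dq),
    }
    return PSAResult(draws=n, seed=seed, quadrants=quadrants, ceac=ceac,
                     intervals=intervals, delta_costs=dc, delta_qalys=dq)
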