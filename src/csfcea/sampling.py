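"""Random parameter draws for probabilistic analysis and a patient-level
microsimulation oracle for the cohort engine.

Distribution families follow standard health-economics practice: beta for
probabilities and utility weights, gamma for rates and costs, lognormal for
hazard ratios, uniform for unclassified coefficients. Each distribution is
parameterized so its mean equals the base-case value and its standard
deviation equals (high - low)/3.92, i.e. the published low/high range is
read as an approximate central 95% interval. Parameters with a zero-width
range are structural constants and are never sampled.

The microsimulation steps individual patients through exactly the same
monthly death/transition probabilities and accrual rules as the cohort
matrices, so the two must agree up to Monte-Carlo error; it exists to
validate the cohort engine, not to replace it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import markov
from .markov import GROUPS, LifetimeOutcome, ScenarioFlags
from .parameters import ParameterSet, ParamValue, iter_params, validate_parameters

__all__ = [
    "DistributionSpec",
    "distribution_for",
    "sample_parameter_set",
    "MicrosimResult",
    "microsimulate_cohort",
]

# "Assumed same as ..." rows co-move with their source row in probabilistic
# draws rather than being sampled independently.
TIED_PARAMS = {
    "mortality.hr_nonad": "mortality.hr_mild",
    "rates.ltcf_nonad": "rates.ltcf_mild",
    "costs.community_nonad": "costs.community_mild",
    "costs.ltcf_nonad": "costs.ltcf_mild",
    "utilities.community_nonad": "utilities.community_mild",
    "utilities.ltcf_nonad": "utilities.ltcf_mild",
}

_FAMILY_BY_KIND = {
    "probability": "beta",
    "utility_weight": "beta",
    "annual_rate_per_100k": "gamma",
    "cost_usd": "gamma",
    "hazard_ratio": "lognormal",
    "coefficient": "uniform",
}


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one parameter."""

    param_id: str
    family: str  # beta | gamma | lognormal | uniform | point
    args: tuple

    def mean(self) -> float:
        f, a = self.family, self.args
        if f == "point":
            return a[0]
        if f == "beta":
            return a[0] / (a[0] + a[1])
        if f == "gamma":
            return a[0] * a[1]
        if f == "lognormal":
            return math.exp(a[0] + a[1] ** 2 / 2.0)
        return (a[0] + a[1]) / 2.0

    def ppf(self, q: float) -> float:
        f, a = self.family, self.args
        if f == "point":
            return a[0]
        if f == "beta":
            return float(stats.beta.ppf(q, a[0], a[1]))
        if f == "gamma":
            return float(stats.gamma.ppf(q, a[0], scale=a[1]))
        if f == "lognormal":
            return float(stats.lognorm.ppf(q, a[1], scale=math.exp(a[0])))
        return a[0] + q * (a[1] - a[0])

    def draw(self, rng: np.random.Generator) -> float:
        f, a = self.family, self.args
        if f == "point":
            return a[0]
        if f == "beta":
            return float(rng.beta(a[0], a[1]))
        if f == "gamma":
            return float(rng.gamma(a[0], a[1]))
        if f == "lognormal":
            return float(rng.lognormal(a[0], a[1]))
        return float(rng.uniform(a[0], a[1]))


def distribution_for(pv: ParamValue, param_id: str = "") -> DistributionSpec:
    """Fit the sampling distribution for one parameter.

    Mean = base value; SD = range width / 3.92. Degenerate ranges give a
    point mass. Beta shape parameters are floored so the density stays
    unimodal even for extreme mean/SD combinations.
    """
    if pv.fixed:
        return DistributionSpec(param_id, "point", (pv.base,))
    sd = (pv.high - pv.low) / 3.92
    family = _FAMILY_BY_KIND[pv.kind]
    if family == "beta":
        mu = pv.base
        if not (0.0 < mu < 1.0):
            return DistributionSpec(param_id, "point", (pv.base,))
        var = min(sd ** 2, 0.95 * mu * (1.0 - mu))
        kappa = mu * (1.0 - mu) / var - 1.0
        alpha = max(mu * kappa, 1e-3)
        beta = max((1.0 - mu) * kappa, 1e-3)
        return DistributionSpec(param_id, "beta", (alpha, beta))
    if family == "gamma":
        if pv.base <= 0:
            return DistributionSpec(param_id, "point", (pv.base,))
        shape = (pv.base / sd) ** 2
        scale = sd ** 2 / pv.base
        return DistributionSpec(param_id, "gamma", (shape, scale))
    if family == "lognormal":
        sigma = math.log(pv.high / pv.low) / 3.92
        mu_log = math.log(pv.base) - sigma ** 2 / 2.0
        return DistributionSpec(param_id, "lognormal", (mu_log, sigma))
    return DistributionSpec(param_id, "uniform", (pv.low, pv.high))


def _sampleable(ps: ParameterSet) -> list[tuple[str, ParamValue]]:
    return [(path, pv) for path, pv in iter_params(ps)
            if not pv.fixed and path not in TIED_PARAMS]


def sample_parameter_set(ps: ParameterSet, rng: np.random.Generator,
                         max_redraws: int = 100) -> ParameterSet:
    """One independent probabilistic draw of every uncertain parameter.

    Parameters are drawn in the stable traversal order of the parameter tree
    (so the same seed yields the same draw), tied "assumed same as" rows are
    copied from their source draw, the initial severity mix is renormalized
    to sum to one, and the whole set is re-validated; a draw violating a hard
    invariant (for example a treatment hazard ratio on the wrong side of 1)
    is redrawn.
    """
    for _ in range(max_redraws):
        out = ps.copy()
        drawn: dict[str, float] = {}
        for path, pv in _sampleable(out):
            spec = distribution_for(pv, path)
            pv.value = spec.draw(rng)
            drawn[path] = pv.value
        for tied, src in TIED_PARAMS.items():
            obj = out
            for part in tied.split("."):
                obj = getattr(obj, part)
            obj.value = drawn.get(src, obj.value)
        mix = out.cohort.severity_mix()
        total = sum(mix)
        out.cohort.mix_mild.value = mix[0] / total
        out.cohort.mix_moderate.value = mix[1] / total
        out.cohort.mix_severe.value = mix[2] / total
        if not _hard_violations(out):
            return out
    raise RuntimeError("could not draw a valid parameter set "
                       f"after {max_redraws} attempts")


def _hard_violations(ps: ParameterSet) -> list[str]:
    # only support-bound violations of drawn values force a redraw; the
    # published low/high range is a soft 95% interval, and base-case
    # direction invariants are not constraints on individual draws
    return [v for v in validate_parameters(ps) if ".value" in v]


@dataclass
class MicrosimResult:
    """Monte-Carlo means with standard errors for one outcome group."""

    n: int
    cost: float
    cost_se: float
    qalys: float
    qalys_se: float
    life_years: float
    life_years_se: float

    def as_outcome(self) -> LifetimeOutcome:
        return LifetimeOutcome(self.cost, self.qalys, self.life_years,
                               float("nan"))


def microsimulate_cohort(group: str, ps: ParameterSet, n: int, seed: int,
                         flags: ScenarioFlags | None = None) -> MicrosimResult:
    """Simulate ``n`` individual patients through the monthly dynamics.

    Each month an individual first faces the age- and severity-specific death
    probability, then (if surviving) samples the next live state from the
    same survival-conditional kernel the cohort model iterates. Discounted
    cost, QALY, and life-year accruals use identical per-cycle rules,
    including the year-of-death cost.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    flags = flags or ScenarioFlags()
    c = markov._compile_group(group, ps, flags)
    rng = np.random.default_rng(seed)
    L = c.init.size
    st = ps.settings
    start_age = ps.cohort.start_age.value
    r = st.discount_rate_annual
    a = ps.mortality.coeff_a.value
    b = ps.mortality.coeff_b.value
    max_cycles = max(1, int(math.ceil((st.max_age - start_age) * 12)))
    mcum = np.cumsum(c.m_live, axis=1)

    state = rng.choice(L, size=n, p=c.init / c.init.sum())
    alive = np.ones(n, dtype=bool)
    cost = np.zeros(n)
    qalys = np.zeros(n)
    ly = np.zeros(n)

    for t in range(max_cycles):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        age = start_age + t / 12.0
        df = (1.0 + r) ** (-t / 12.0)
        bc = ps.costs.baseline_coeff_a.value * math.exp(
            ps.costs.baseline_coeff_b.value * age)
        if age >= 90:
            bc = min(bc, ps.costs.baseline_cap.value)
        s = state[idx]
        cost[idx] += df * (bc + c.excess_cost[s] + c.drug_cost[s]) / 12.0
        agew = ps.utilities.age_weight(age)
        qalys[idx] += df * (agew * c.state_util[s] + c.util_incr[s]) / 12.0
        ly[idx] += df / 12.0

        pd = 1.0 - np.exp(-a * math.exp(b * age) * c.hr_mort[s] / 1e5 / 12.0)
        u = rng.random(idx.size)
        dies = u < pd
        dcost = (ps.costs.death_under90.value if age < 90
                 else ps.costs.death_over90.value)
        cost[idx[dies]] += df * dcost
        alive[idx[dies]] = False
        surv = idx[~dies]
        if surv.size:
            rows = mcum[state[surv]]
            u2 = rng.random(surv.size)
            state[surv] = (u2[:, None] < rows).argmax(axis=1)

    def mse(x):
        return float(x.mean()), float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0

    (cm, cs), (qm, qs), (lm, ls) = mse(cost), mse(qalys), mse(ly)
    return MicrosimResult(n=n, cost=cm, cost_se=cs, qalys=qm, qalys_se=qs,
                          life_years=lm, life_years_se=ls)
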