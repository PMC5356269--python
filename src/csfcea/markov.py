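"""Monthly-cycle Markov cohort model of AD and non-AD trajectories.

Patients with AD occupy 12 live states (severity mild/moderate/severe x
location community/long-term-care-facility x on/off treatment); patients
without AD occupy 4 live states (location x treatment); death is absorbing.
Each month a patient may die, progress or regress in severity, move from the
community into an LTCF (never back), and start or stop treatment.

Event composition within a cycle
--------------------------------
Death is applied first from the start-of-cycle state; conditional on
survival, the severity, location, and treatment-status kernels are composed
in that order. Each competing hazard is converted independently to a monthly
probability ``1 - exp(-h/12)`` with the self-loop absorbing the remainder
(at monthly cycles the difference from a joint competing-risks split is far
below every other source of uncertainty). No half-cycle correction is
applied: costs and utilities accrue for the full month in the start-of-cycle
state.

Treatment dynamics
------------------
Donepezil treats mild/moderate AD (and falsely diagnosed non-AD patients);
memantine treats severe AD. Treated-state hazards are off-treatment hazards
times the treatment hazard ratios (mild->moderate x0.5, moderate->mild
x2.36, community->LTCF x0.37 while on donepezil). On transition into severe AD, on-donepezil
patients switch to memantine with the memantine uptake probability and
otherwise stop treatment; off-treatment severe patients may reinitiate at
the memantine reinitiation hazard. Treatment never affects mortality.
Falsely diagnosed (FP) patients accrue treatment costs but their hazard
modifications are scaled by ``fp_benefit_fraction`` (0 in the base case,
i.e. no benefit).

Cost accrual
------------
Every live patient accrues the age-specific baseline cost
``893 * exp(0.0404 * age)`` (capped at $33,870/yr from age 90). Disease
severity adds the published incremental cost in excess of the common
mild/non-AD care level; LTCF residence adds the facility cost plus the
LTCF medical increment net of the mild level. This excess-over-mild
convention is what reproduces the published lifetime discounted costs;
accruing the full printed community increments on top of the baseline curve
does not (see docs/methods.md). Treated patients add the annual drug cost;
the year-of-death cost is added once in the cycle of death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "GROUPS",
    "HealthState",
    "ScenarioFlags",
    "LifetimeOutcome",
    "ad_states",
    "nonad_states",
    "annual_hazard_to_cycle_prob",
    "other_cause_mortality_rate",
    "cycle_death_prob",
    "baseline_annual_cost",
    "cycle_cost",
    "cycle_utility",
    "build_cycle_transition_matrix",
    "run_cohort",
    "run_all_groups",
]

GROUPS = ("TP", "FN", "FP", "TN")
_SEV_NAMES = ("mild", "moderate", "severe")
_LOC_NAMES = ("community", "ltcf")


@dataclass(frozen=True)
class HealthState:
    group: str  # "AD", "nonAD", "dead"
    severity: Optional[str] = None  # mild/moderate/severe or None
    location: Optional[str] = None  # community/ltcf or None
    on_treatment: bool = False

    def __str__(self) -> str:
        if self.group == "dead":
            return "dead"
        sev = f"{self.severity}_" if self.severity else ""
        tx = "tx" if self.on_treatment else "notx"
        return f"{self.group}_{sev}{self.location}_{tx}"


def ad_states() -> list[HealthState]:
    """The 12 live AD states in engine order (sev fastest, then loc, then tx)."""
    return [HealthState("AD", _SEV_NAMES[s], _LOC_NAMES[l], bool(tx))
            for tx in (0, 1) for l in (0, 1) for s in (0, 1, 2)]


def nonad_states() -> list[HealthState]:
    """The 4 live non-AD states in engine order."""
    return [HealthState("nonAD", None, _LOC_NAMES[l], bool(tx))
            for tx in (0, 1) for l in (0, 1)]


@dataclass(frozen=True)
class ScenarioFlags:
    """Structural scenario switches (base case = all defaults)."""

    nonad_history: str = "stable_mild"  # stable_mild | stable_moderate | progressive_like_ad
    fn_correction_on_progression: bool = False
    donepezil_affects_moderate_to_severe: bool = False

    def __post_init__(self):
        allowed = ("stable_mild", "stable_moderate", "progressive_like_ad")
        if self.nonad_history not in allowed:
            raise ValueError(f"nonad_history must be one of {allowed}")


@dataclass
class LifetimeOutcome:
    """Per-patient lifetime totals for one diagnostic-outcome group.

    ``life_years`` is discounted at the same annual rate as costs and QALYs,
    matching the published convention; the undiscounted total is carried
    alongside.
    """

    discounted_cost: float
    discounted_qalys: float
    life_years: float
    life_years_undiscounted: float
    trace: Optional["np.ndarray"] = field(default=None, repr=False)
    trace_columns: Optional[list[str]] = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# elementary quantities

def annual_hazard_to_cycle_prob(rate_per_100k: float, cycle_months: float = 1.0) -> float:
    """Convert an annual hazard on the per-100,000 scale to a cycle probability."""
    if rate_per_100k < 0:
        raise ValueError(f"negative rate: {rate_per_100k}")
    return 1.0 - math.exp(-(rate_per_100k / 1e5) * (cycle_months / 12.0))


def other_cause_mortality_rate(age: float, ps: ParameterSet | None = None) -> float:
    """Annual non-AD mortality rate per 100,000 at a given age (exponential fit)."""
    if age < 0:
        raise ValueError("age must be >= 0")
    if ps is None:
        a, b = 3.53, 0.0909
    else:
        a = ps.mortality.coeff_a.value
        b = ps.mortality.coeff_b.value
    return a * math.exp(b * age)


def _mortality_hr(state: HealthState, ps: ParameterSet) -> float:
    m = ps.mortality
    if state.group == "nonAD":
        return m.hr_nonad.value
    return {"mild": m.hr_mild.value, "moderate": m.hr_moderate.value,
            "severe": m.hr_severe.value}[state.severity]


def cycle_death_prob(age: float, state: HealthState, ps: ParameterSet,
                     cycle_months: float = 1.0) -> float:
    """Monthly death probability: other-cause rate times the severity HR.

    Identical for on- and off-treatment states (treatment does not affect
    mortality).
    """
    if state.group == "dead":
        raise ValueError("death probability undefined for the dead state")
    hazard = other_cause_mortality_rate(age, ps) * _mortality_hr(state, ps)
    return annual_hazard_to_cycle_prob(hazard, cycle_months)


def baseline_annual_cost(age: float, ps: ParameterSet) -> float:
    """Age-specific annual health care cost unrelated to AD, capped from age 90."""
    if age < 0:
        raise ValueError("age must be >= 0")
    c = ps.costs
    raw = c.baseline_coeff_a.value * math.exp(c.baseline_coeff_b.value * age)
    if age >= 90:
        return min(raw, c.baseline_cap.value)
    return raw


def _excess_cost(sev_key: str, location: str, ps: ParameterSet) -> float:
    """Disease/location cost increment in excess of the common care level.

    The mild/non-AD community increment (dominated by supportive and informal
    care every patient in this evaluated population receives) is treated as
    the common care level. Community residents accrue the severity increment
    in excess of it; LTCF residents accrue the facility cost plus the LTCF
    medical increment, which together displace that community-level care.
    This reading reproduces the published lifetime discounted costs; accruing
    the full printed community increments on top of the age-baseline curve
    does not (see docs/methods.md).
    """
    c = ps.costs
    comm = {"nonad": c.community_nonad, "mild": c.community_mild,
            "moderate": c.community_moderate, "severe": c.community_severe}
    ltcf = {"nonad": c.ltcf_nonad, "mild": c.ltcf_mild,
            "moderate": c.ltcf_moderate, "severe": c.ltcf_severe}
    if location == "community":
        return comm[sev_key].value - c.community_mild.value
    return c.ltcf_facility.value + ltcf[sev_key].value - c.community_mild.value


def _drug_annual(state: HealthState, ps: ParameterSet) -> float:
    if not state.on_treatment:
        return 0.0
    if state.group == "AD" and state.severity == "severe":
        return ps.costs.memantine_annual.value
    return ps.costs.donepezil_annual.value


def cycle_cost(state: HealthState, age: float, ps: ParameterSet,
               nonad_severity: str = "nonad") -> float:
    """Monthly cost of occupying a live state; the dead state accrues nothing."""
    if state.group == "dead":
        return 0.0
    sev_key = state.severity if state.group == "AD" else nonad_severity
    annual = (baseline_annual_cost(age, ps)
              + _excess_cost(sev_key, state.location, ps)
              + _drug_annual(state, ps))
    return annual / 12.0


def _state_utility_weight(state: HealthState, ps: ParameterSet,
                          nonad_severity: str = "nonad") -> float:
    u = ps.utilities
    key = state.severity if state.group == "AD" else nonad_severity
    table = {
        ("community", "nonad"): u.community_nonad, ("ltcf", "nonad"): u.ltcf_nonad,
        ("community", "mild"): u.community_mild, ("ltcf", "mild"): u.ltcf_mild,
        ("community", "moderate"): u.community_moderate, ("ltcf", "moderate"): u.ltcf_moderate,
        ("community", "severe"): u.community_severe, ("ltcf", "severe"): u.ltcf_severe,
    }
    return table[(state.location, key)].value


def cycle_utility(state: HealthState, age: float, ps: ParameterSet,
                  efficacy: float = 1.0) -> float:
    """Monthly QALY accrual: age-band weight x state weight, plus the
    annualized memantine increment for severe AD on treatment."""
    if state.group == "dead":
        return 0.0
    q = ps.utilities.age_weight(age) * _state_utility_weight(state, ps)
    if state.group == "AD" and state.severity == "severe" and state.on_treatment:
        q += ps.treatment.memantine_utility.value * efficacy
    return q / 12.0


# ---------------------------------------------------------------------------
# compiled cohort dynamics

def _hr_eff(hr: float, efficacy: float) -> float:
    """Scale a treatment hazard ratio toward 1 by the efficacy fraction."""
    return 1.0 + efficacy * (hr - 1.0)


def _p(rate: float) -> float:
    return 1.0 - math.exp(-rate / 1e5 / 12.0)


class _Compiled:
    """Age-independent monthly dynamics for one diagnostic-outcome group."""

    def __init__(self, states: list[HealthState], m_live: np.ndarray,
                 hr_mort: np.ndarray, excess_cost: np.ndarray, drug_cost: np.ndarray,
                 state_util: np.ndarray, util_incr: np.ndarray, init: np.ndarray):
        self.states = states
        self.m_live = m_live          # (L, L) conditional on survival
        self.hr_mort = hr_mort
        self.excess_cost = excess_cost
        self.drug_cost = drug_cost
        self.state_util = state_util
        self.util_incr = util_incr
        self.init = init


def _tx_kernel(old_sev: int, new_sev: int, new_loc: int, on: bool, *,
               treated: bool, fn_correct: bool, t, efficacy: float) -> dict[bool, float]:
    """P(new treatment status | severity path, destination location)."""
    if not treated:
        if not on:
            if fn_correct and new_sev > old_sev:
                # re-diagnosis on progression: uptake applies at that moment
                up = (t.donepezil_uptake.value if new_sev == 1
                      else t.memantine_uptake.value)
                return {True: up, False: 1.0 - up}
            return {False: 1.0}
        if not fn_correct:
            # never-treated groups hold no on-treatment mass, but the kernel
            # must still be stochastic for matrix-level invariants
            return {True: 1.0}
        # corrected false-negatives discontinue like any treated patient;
        # reinitiation is not modelled for them (diagnosis status and
        # treatment history are not separate state dimensions)
    if new_sev == 2 and old_sev != 2:
        # entering severe AD: donepezil stops; patients on treatment switch
        # to memantine with the memantine uptake probability
        if on:
            up = t.memantine_uptake.value
            return {True: up, False: 1.0 - up}
        return {False: 1.0}
    if new_sev == 2:
        disc = _p(t.disc_memantine.value)
        reinit = _p(t.reinit_memantine.value)
    else:
        disc = _p(t.disc_donepezil_ltcf.value if new_loc == 1
                  else t.disc_donepezil_community.value)
        reinit = _p(t.reinit_donepezil.value)
    if on:
        return {True: 1.0 - disc, False: disc}
    return {True: reinit, False: 1.0 - reinit}


def _compile_ad(ps: ParameterSet, flags: ScenarioFlags, *, treated: bool,
                efficacy: float, init_on: Optional[float],
                fn_correct: bool = False) -> _Compiled:
    """Build the 12-state AD dynamics (also reused for progressive non-AD)."""
    r, t, u = ps.rates, ps.treatment, ps.utilities
    states = ad_states()
    idx = {(s, l, tx): s + 3 * l + 6 * tx for tx in (0, 1) for l in (0, 1)
           for s in (0, 1, 2)}
    L = 12

    prog = {  # severity hazards per 100k/yr, off treatment
        (0, 1): r.mild_to_moderate.value, (0, 2): r.mild_to_severe.value,
        (1, 0): r.moderate_to_mild.value, (1, 2): r.moderate_to_severe.value,
        (2, 0): r.severe_to_mild.value, (2, 1): r.severe_to_moderate.value,
    }
    ltcf_rate = [r.ltcf_mild.value, r.ltcf_moderate.value, r.ltcf_severe.value]

    hr_m2mo = _hr_eff(t.hr_mild_to_moderate.value, efficacy)
    hr_mo2m = _hr_eff(t.hr_moderate_to_mild.value, efficacy)
    hr_mo2s = (hr_m2mo if flags.donepezil_affects_moderate_to_severe else 1.0)
    hr_ltcf_don = _hr_eff(t.hr_community_to_ltcf.value, efficacy)
    hr_ltcf_mem = _hr_eff(t.hr_community_to_ltcf_memantine.value, efficacy)

    m = np.zeros((L, L))
    for (sev, loc, on), i in idx.items():
        # severity kernel
        sev_p: dict[int, float] = {}
        for (a, b), rate in prog.items():
            if a != sev:
                continue
            h = rate
            if on:
                if (a, b) == (0, 1):
                    h *= hr_m2mo
                elif (a, b) == (1, 0):
                    h *= hr_mo2m
                elif (a, b) == (1, 2):
                    h *= hr_mo2s
            sev_p[b] = _p(h)
        sev_p[sev] = 1.0 - sum(sev_p.values())
        # location kernel (keyed to start-of-cycle severity)
        if loc == 0:
            h = ltcf_rate[sev]
            if on:
                h *= hr_ltcf_mem if sev == 2 else hr_ltcf_don
            p_ltcf = _p(h)
            loc_p = {0: 1.0 - p_ltcf, 1: p_ltcf}
        else:
            loc_p = {1: 1.0}
        for new_sev, p_s in sev_p.items():
            for new_loc, p_l in loc_p.items():
                txk = _tx_kernel(sev, new_sev, new_loc, bool(on), treated=treated,
                                 fn_correct=fn_correct, t=t, efficacy=efficacy)
                for new_on, p_t in txk.items():
                    m[i, idx[(new_sev, new_loc, int(new_on))]] += p_s * p_l * p_t

    mo = ps.mortality
    hrs = [mo.hr_mild.value, mo.hr_moderate.value, mo.hr_severe.value]
    hr_mort = np.array([hrs[i % 3] for i in range(L)])

    excess = np.array([_excess_cost(_SEV_NAMES[i % 3],
                                    _LOC_NAMES[(i // 3) % 2], ps) for i in range(L)])
    drug = np.array([(ps.costs.memantine_annual.value if i % 3 == 2
                      else ps.costs.donepezil_annual.value) if i >= 6 else 0.0
                     for i in range(L)])
    comm_u = [u.community_mild.value, u.community_moderate.value, u.community_severe.value]
    ltcf_u = [u.ltcf_mild.value, u.ltcf_moderate.value, u.ltcf_severe.value]
    state_u = np.array([(ltcf_u if (i // 3) % 2 else comm_u)[i % 3] for i in range(L)])
    util_incr = np.array([t.memantine_utility.value * efficacy
                          if (i >= 6 and i % 3 == 2) else 0.0 for i in range(L)])

    init = np.zeros(L)
    mix = ps.cohort.severity_mix()
    if init_on is None:
        for s in range(3):
            init[s] = mix[s]
    else:
        up = [t.donepezil_uptake.value, t.donepezil_uptake.value,
              t.memantine_uptake.value]
        for s in range(3):
            init[s] = mix[s] * (1.0 - up[s])
            init[6 + s] = mix[s] * up[s]
    return _Compiled(states, m, hr_mort, excess, drug, state_u, util_incr, init)


def _compile_nonad(ps: ParameterSet, flags: ScenarioFlags, *, treated: bool,
                   efficacy: float, init_on: Optional[float]) -> _Compiled:
    """Build the 4-state non-AD dynamics for the stable-history scenarios."""
    t, u = ps.treatment, ps.utilities
    if flags.nonad_history == "stable_moderate":
        sev_key = "moderate"
        ltcf_rate = ps.rates.ltcf_moderate.value
        hr_mort_v = ps.mortality.hr_moderate.value
    else:
        sev_key = "nonad"
        ltcf_rate = ps.rates.ltcf_nonad.value
        hr_mort_v = ps.mortality.hr_nonad.value

    states = nonad_states()
    idx = {(l, tx): l + 2 * tx for tx in (0, 1) for l in (0, 1)}
    L = 4
    hr_ltcf = _hr_eff(t.hr_community_to_ltcf.value, efficacy)

    m = np.zeros((L, L))
    for (loc, on), i in idx.items():
        if loc == 0:
            h = ltcf_rate * (hr_ltcf if on else 1.0)
            p_l = _p(h)
            loc_p = {0: 1.0 - p_l, 1: p_l}
        else:
            loc_p = {1: 1.0}
        for new_loc, p_loc in loc_p.items():
            if not treated:
                txk = {bool(on): 1.0}
            else:
                disc = _p(t.disc_donepezil_ltcf.value if new_loc == 1
                          else t.disc_donepezil_community.value)
                reinit = _p(t.reinit_donepezil.value)
                txk = ({True: 1.0 - disc, False: disc} if on
                       else {True: reinit, False: 1.0 - reinit})
            for new_on, p_t in txk.items():
                m[i, idx[(new_loc, int(new_on))]] += p_loc * p_t

    hr_mort = np.full(L, hr_mort_v)
    excess = np.array([_excess_cost(sev_key, _LOC_NAMES[i % 2], ps) for i in range(L)])
    drug = np.array([ps.costs.donepezil_annual.value if i >= 2 else 0.0
                     for i in range(L)])
    table = {"nonad": (u.community_nonad.value, u.ltcf_nonad.value),
             "moderate": (u.community_moderate.value, u.ltcf_moderate.value)}
    state_u = np.array([table[sev_key][i % 2] for i in range(L)])
    util_incr = np.zeros(L)

    init = np.zeros(L)
    if init_on is None:
        init[0] = 1.0
    else:
        init[0] = 1.0 - init_on
        init[2] = init_on
    return _Compiled(states, m, hr_mort, excess, drug, state_u, util_incr, init)


def _compile_group(group: str, ps: ParameterSet, flags: ScenarioFlags) -> _Compiled:
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    t = ps.treatment
    if group == "TP":
        return _compile_ad(ps, flags, treated=True, efficacy=1.0,
                           init_on=t.donepezil_uptake.value)
    if group == "FN":
        return _compile_ad(ps, flags, treated=False, efficacy=1.0, init_on=None,
                           fn_correct=flags.fn_correction_on_progression)
    f = t.fp_benefit_fraction.value
    if flags.nonad_history == "progressive_like_ad":
        if group == "FP":
            return _compile_ad(ps, flags, treated=True, efficacy=f,
                               init_on=t.donepezil_uptake.value)
        return _compile_ad(ps, flags, treated=False, efficacy=0.0, init_on=None)
    if group == "FP":
        return _compile_nonad(ps, flags, treated=True, efficacy=f,
                              init_on=t.donepezil_uptake.value)
    return _compile_nonad(ps, flags, treated=False, efficacy=0.0, init_on=None)


def build_cycle_transition_matrix(age: float, group: str, ps: ParameterSet,
                                  flags: ScenarioFlags | None = None) -> np.ndarray:
    """Full row-stochastic monthly transition matrix (live states + dead last).

    Composes the age-specific death probability with the compiled
    survival-conditional dynamics; raises if any row deviates from sum 1 by
    more than 1e-10.
    """
    flags = flags or ScenarioFlags()
    c = _compile_group(group, ps, flags)
    L = len(c.init)
    h0 = other_cause_mortality_rate(age, ps)
    pd = 1.0 - np.exp(-h0 * c.hr_mort / 1e5 / 12.0)
    full = np.zeros((L + 1, L + 1))
    full[:L, :L] = (1.0 - pd)[:, None] * c.m_live
    full[:L, L] = pd
    full[L, L] = 1.0
    rows = full.sum(axis=1)
    if np.abs(rows - 1.0).max() > 1e-10:
        raise AssertionError(f"non-stochastic transition row: {rows}")
    return full


def run_cohort(group: str, ps: ParameterSet,
               flags: ScenarioFlags | None = None,
               keep_trace: bool = False) -> LifetimeOutcome:
    """Follow one diagnostic-outcome cohort from diagnosis to death.

    Iterates the monthly transition dynamics from the start age until the
    cohort is (numerically) extinct or reaches the maximum age, accruing
    discounted costs and QALYs with per-cycle discount factor
    ``(1 + r)^(-month/12)`` and adding the age-dependent year-of-death cost
    in the cycle of death.
    """
    flags = flags or ScenarioFlags()
    c = _compile_group(group, ps, flags)
    st = ps.settings
    start_age = ps.cohort.start_age.value
    r = st.discount_rate_annual
    max_cycles = max(1, int(math.ceil((st.max_age - start_age) * 12)))

    a = ps.mortality.coeff_a.value
    b = ps.mortality.coeff_b.value
    mt = c.m_live.T.copy()
    occ = c.init.copy()
    L = occ.size

    hist = np.zeros((max_cycles, L))
    deaths = np.zeros(max_cycles)
    n = 0
    for tcycle in range(max_cycles):
        live = occ.sum()
        if live < 1e-9:
            break
        hist[tcycle] = occ
        age = start_age + tcycle / 12.0
        surv = occ * np.exp(-a * math.exp(b * age) * c.hr_mort / 1e5 / 12.0)
        deaths[tcycle] = live - surv.sum()
        occ = mt @ surv
        n = tcycle + 1

    hist = hist[:n]
    deaths = deaths[:n]
    tt = np.arange(n)
    ages = start_age + tt / 12.0
    df = (1.0 + r) ** (-tt / 12.0)

    bc = np.minimum(
        ps.costs.baseline_coeff_a.value * np.exp(ps.costs.baseline_coeff_b.value * ages),
        np.where(ages >= 90, ps.costs.baseline_cap.value, np.inf))
    live_mass = hist.sum(axis=1)
    cycle_costs = (bc * live_mass + hist @ (c.excess_cost + c.drug_cost)) / 12.0
    death_cost = np.where(ages < 90, ps.costs.death_under90.value,
                          ps.costs.death_over90.value)
    cycle_costs = cycle_costs + deaths * death_cost

    agew = np.array([ps.utilities.age_weight(x) for x in ages])
    cycle_qalys = (agew * (hist @ c.state_util) + hist @ c.util_incr) / 12.0

    # mass conservation: live + cumulative dead must stay at 1
    total = live_mass + np.concatenate(([0.0], np.cumsum(deaths)[:-1]))
    if n and np.abs(total - 1.0).max() > 1e-10:
        raise AssertionError("cohort mass not conserved")

    out = LifetimeOutcome(
        discounted_cost=float(df @ cycle_costs),
        discounted_qalys=float(df @ cycle_qalys),
        life_years=float(df @ live_mass) / 12.0,
        life_years_undiscounted=float(live_mass.sum()) / 12.0,
    )
    if keep_trace:
        cols = (["month", "age", "discount_factor"]
                + [str(s) for s in c.states]
                + ["cycle_cost", "cycle_qaly"])
        out.trace = np.column_stack([tt, ages, df, hist, cycle_costs, cycle_qalys])
        out.trace_columns = cols
    return out


def run_all_groups(ps: ParameterSet,
                   flags: ScenarioFlags | None = None) -> dict[str, LifetimeOutcome]:
    """Lifetime outcomes for all four diagnostic-outcome groups."""
    return {g: run_cohort(g, ps, flags) for g in GROUPS}
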