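"""Tunnel-expanded Markov cohort engine.

The cohort starts in progressive disease (PD) on first-line chemotherapy.
Response is resolved at the end of the first-line evaluation window
(cycle 3): the PD mass splits into CR/PR/SD tunnels — chains of one-month
compartments whose length is the regimen's median response duration
rounded half-up to whole months — or stays in PD and switches to
second-line treatment.  Second-line response resolves three cycles after
the switch against the probability-weighted mixture of the country's
second-line regimens.  Patients relapsing from a second-line response, or
failing second line, receive palliative care only.  Background (age-
related) mortality applies everywhere; cancer-related mortality applies
only in PD-type compartments (on-treatment PD and palliative care).

Within a cycle, death competes first; response resolution and tunnel
advance act on survivors.  The same event ordering is used by the
patient-level microsimulation oracle in :mod:`sarcoma_cea.synthetic`.

Occupancy convention: ``occupancy[t]`` (1-based cycles ``t = 1..24``) is
the distribution *during* month ``t``.  The cohort spends month 1 in the
first treatment cycle; each later month applies one transition.  The
two-year end state is one further transition beyond month 24.  Utility
accrues as occupancy-weighted state utility divided by 12, with
second-year cycles (13-24) discounted by a single-step factor 1/1.03.
No half-cycle correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .parameters import (
    EfficacyProfile,
    ModelParameters,
    ParameterError,
    ToxicityProfile,
    UtilitySet,
    ModelConstants,
)
from .survival import mixture_hazard

__all__ = [
    "Compartment",
    "StateSpace",
    "SecondLineAggregate",
    "CohortTrajectory",
    "round_half_up",
    "tunnel_length",
    "second_line_aggregate",
    "build_state_space",
    "transition_step",
    "run_cohort",
    "compute_qalys",
]

#: Mass-conservation tolerance checked at every cycle.
MASS_TOL = 1e-12


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves rounding up."""
    return int(math.floor(x + 0.5))


def tunnel_length(median_months: float) -> int:
    """Tunnel length in whole monthly cycles for a median response duration."""
    if median_months < 0:
        raise ValueError("duration must be non-negative")
    return round_half_up(median_months)


@dataclass(frozen=True)
class Compartment:
    """One compartment of the tunnel-expanded state space.

    ``successors`` lists (index, probability) pairs over survivors; every
    non-absorbing compartment's successor probabilities sum to one.
    ``course_cycle`` is the 1-based chemotherapy-course cycle when the
    compartment is on treatment, 0 otherwise.
    """

    name: str
    state: str  # CR / PR / SD / PD / DEAD
    line: str  # first / second / palliative / none
    phase: str  # treatment / tunnel / palliative / dead
    cancer_hazard: float
    on_treatment: bool = False
    course_cycle: int = 0
    tunnel_pos: int = 0
    successors: tuple[tuple[int, float], ...] = ()


@dataclass(frozen=True)
class SecondLineAggregate:
    """Mix-weighted second-line profile for a first-line strategy."""

    efficacy: EfficacyProfile
    toxicity: ToxicityProfile
    hazard: float


def second_line_aggregate(
    params: ModelParameters, first_line: str
) -> SecondLineAggregate:
    """Aggregate second-line efficacy/toxicity/hazard over the country mix."""
    mix = params.mix_for(first_line)
    eff = {n: params.efficacy[(n, "second")] for n in mix.entries}
    tox = {n: params.toxicity[(n, "second")] for n in mix.entries}

    def wmean(get) -> float:
        return sum(w * get(n) for n, w in mix.entries.items())

    probs = np.array(
        [
            wmean(lambda n: eff[n].p_cr),
            wmean(lambda n: eff[n].p_pr),
            wmean(lambda n: eff[n].p_sd),
            wmean(lambda n: eff[n].p_pd),
        ]
    )
    probs = probs / probs.sum()
    efficacy = EfficacyProfile(
        p_cr=float(probs[0]),
        p_pr=float(probs[1]),
        p_sd=float(probs[2]),
        p_pd=float(probs[3]),
        dur_cr=wmean(lambda n: eff[n].dur_cr),
        dur_pr=wmean(lambda n: eff[n].dur_pr),
        dur_sd=wmean(lambda n: eff[n].dur_sd),
    )
    toxicity = ToxicityProfile(
        p_neutropenia=wmean(lambda n: tox[n].p_neutropenia),
        p_febrile_neutropenia=wmean(lambda n: tox[n].p_febrile_neutropenia),
        p_thrombocytopenia=wmean(lambda n: tox[n].p_thrombocytopenia),
        p_anaemia=wmean(lambda n: tox[n].p_anaemia),
    )
    hazard = mixture_hazard(
        mix, {n: params.hazards[(n, "second")] for n in mix.entries}
    )
    return SecondLineAggregate(efficacy=efficacy, toxicity=toxicity, hazard=hazard)


@dataclass
class StateSpace:
    """Tunnel-expanded compartments plus cached propagation structure."""

    strategy: str
    include_second_line: bool
    compartments: tuple[Compartment, ...]
    entry: int
    dead: int
    palliative: int
    second_line: SecondLineAggregate | None
    index: dict[str, int] = field(init=False)
    movement: np.ndarray = field(init=False)  # column-stochastic over survivors
    cancer_hazard: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.index = {c.name: i for i, c in enumerate(self.compartments)}
        n = len(self.compartments)
        M = np.zeros((n, n))
        for j, comp in enumerate(self.compartments):
            for i, p in comp.successors:
                M[i, j] += p
            colsum = M[:, j].sum()
            if abs(colsum - 1.0) > 1e-9:
                raise ParameterError(
                    f"compartment {comp.name}: successor probabilities sum to {colsum}"
                )
        self.movement = M
        self.cancer_hazard = np.array(
            [c.cancer_hazard for c in self.compartments]
        )

    @property
    def n(self) -> int:
        return len(self.compartments)

    def initial_occupancy(self) -> np.ndarray:
        occ = np.zeros(self.n)
        occ[self.entry] = 1.0
        return occ


def _resolution_successors(
    profile: EfficacyProfile,
    tunnel_entries: Mapping[str, int | None],
    pd_target: int,
) -> tuple[tuple[int, float], ...]:
    """Successor distribution for an evaluation compartment.

    Responses whose tunnel has zero length fall through directly to the
    next line's PD compartment.
    """
    out: dict[int, float] = {}
    for state, p in zip(("CR", "PR", "SD"), (profile.p_cr, profile.p_pr, profile.p_sd)):
        target = tunnel_entries.get(state)
        idx = pd_target if target is None else target
        out[idx] = out.get(idx, 0.0) + p
    out[pd_target] = out.get(pd_target, 0.0) + profile.p_pd
    return tuple(out.items())


def build_state_space(
    params: ModelParameters,
    strategy: str,
    include_second_line: bool = True,
) -> StateSpace:
    """Construct the tunnel-expanded state space for a first-line strategy."""
    if (strategy, "first") not in params.efficacy:
        raise ParameterError(f"no first-line efficacy profile for {strategy!r}")
    const = params.constants
    eff1 = params.efficacy[(strategy, "first")]
    h1 = params.hazards[(strategy, "first")]
    agg2 = second_line_aggregate(params, strategy) if include_second_line else None

    comps: list[Compartment] = []

    def add(comp: Compartment) -> int:
        comps.append(comp)
        return len(comps) - 1

    # allocate indices bottom-up so successors are known: DEAD, palliative,
    # then line 2 (treatment + tunnels), then line 1, then entry chain.
    dead = add(
        Compartment("DEAD", "DEAD", "none", "dead", 0.0, successors=((0, 1.0),))
    )
    # palliative PD: cancer hazard continues at the failed line's rate
    pall_hazard = agg2.hazard if agg2 is not None else h1
    pall = add(
        Compartment(
            "PALLIATIVE", "PD", "palliative", "palliative", pall_hazard,
            successors=((1, 1.0),),
        )
    )

    def build_tunnels(
        line: str, profile: EfficacyProfile, exit_idx: int, on_treat_cycles: int,
        course_offset: int,
    ) -> dict[str, int | None]:
        """Create tunnel chains; returns entry index per response state."""
        entries: dict[str, int | None] = {}
        for state, dur in zip(("CR", "PR", "SD"), profile.durations):
            length = tunnel_length(dur)
            if length == 0:
                entries[state] = None
                continue
            idxs: list[int] = []
            for pos in range(1, length + 1):
                on_treat = pos <= on_treat_cycles
                idxs.append(
                    add(
                        Compartment(
                            f"{state}{'1' if line == 'first' else '2'}_t{pos}",
                            state,
                            line,
                            "tunnel",
                            0.0,
                            on_treatment=on_treat,
                            course_cycle=course_offset + pos if on_treat else 0,
                            tunnel_pos=pos,
                        )
                    )
                )
            # wire the chain
            for k, idx in enumerate(idxs):
                nxt = idxs[k + 1] if k + 1 < len(idxs) else exit_idx
                comps[idx] = _with_successors(comps[idx], ((nxt, 1.0),))
            entries[state] = idxs[0]
        return entries

    # responders continue treatment to the mean course length
    extra1 = max(const.mean_course_cycles - const.first_line_switch_cycle, 0)
    extra2 = max(const.mean_course_cycles - const.second_line_eval_cycles, 0)

    if agg2 is not None:
        # second-line treatment chain placeholder indices
        pd2_idx: list[int] = []
        for cyc in range(1, const.second_line_eval_cycles + 1):
            pd2_idx.append(
                add(
                    Compartment(
                        f"PD2_c{cyc}", "PD", "second", "treatment", agg2.hazard,
                        on_treatment=True, course_cycle=cyc,
                    )
                )
            )
        tunnels2 = build_tunnels("second", agg2.efficacy, pall, extra2,
                                 const.second_line_eval_cycles)
        for k, idx in enumerate(pd2_idx):
            if k + 1 < len(pd2_idx):
                comps[idx] = _with_successors(comps[idx], ((pd2_idx[k + 1], 1.0),))
            else:
                comps[idx] = _with_successors(
                    comps[idx], _resolution_successors(agg2.efficacy, tunnels2, pall)
                )
        after_first_line = pd2_idx[0]
    else:
        after_first_line = pall

    tunnels1 = build_tunnels("first", eff1, after_first_line, extra1,
                             const.first_line_switch_cycle)

    pd1_idx: list[int] = []
    for cyc in range(1, const.first_line_switch_cycle + 1):
        pd1_idx.append(
            add(
                Compartment(
                    f"PD1_c{cyc}", "PD", "first", "treatment", h1,
                    on_treatment=True, course_cycle=cyc,
                )
            )
        )
    for k, idx in enumerate(pd1_idx):
        if k + 1 < len(pd1_idx):
            comps[idx] = _with_successors(comps[idx], ((pd1_idx[k + 1], 1.0),))
        else:
            comps[idx] = _with_successors(
                comps[idx],
                _resolution_successors(eff1, tunnels1, after_first_line),
            )

    return StateSpace(
        strategy=strategy,
        include_second_line=include_second_line,
        compartments=tuple(comps),
        entry=pd1_idx[0],
        dead=dead,
        palliative=pall,
        second_line=agg2,
    )


def _with_successors(
    comp: Compartment, successors: tuple[tuple[int, float], ...]
) -> Compartment:
    return Compartment(
        name=comp.name,
        state=comp.state,
        line=comp.line,
        phase=comp.phase,
        cancer_hazard=comp.cancer_hazard,
        on_treatment=comp.on_treatment,
        course_cycle=comp.course_cycle,
        tunnel_pos=comp.tunnel_pos,
        successors=successors,
    )


def _survival_factors(
    space: StateSpace, params: ModelParameters, cycle: int
) -> np.ndarray:
    """Per-compartment one-cycle survival probability entering ``cycle``."""
    age = 65.0 + (cycle - 1) / 12.0
    h_bg = params.life_table.monthly_hazard(age)
    total = h_bg + space.cancer_hazard
    factors = np.exp(-total)
    factors[space.dead] = 1.0
    return factors


def transition_step(
    occupancy: np.ndarray,
    cycle: int,
    space: StateSpace,
    params: ModelParameters,
) -> np.ndarray:
    """One monthly transition: death first, then movement among survivors.

    ``cycle`` is the (1-based) month being entered; background mortality is
    taken from the life table at the cohort's age during that month.
    """
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (space.n,):
        raise ValueError("occupancy has wrong shape")
    survive = _survival_factors(space, params, cycle)
    alive = occ * survive
    dead_new = occ - alive
    out = space.movement @ alive
    out[space.dead] += dead_new.sum()
    total = out.sum()
    if abs(total - occ.sum()) > MASS_TOL * max(1.0, occ.sum()):
        raise AssertionError(f"mass not conserved at cycle {cycle}: {total}")
    return out


@dataclass
class CohortTrajectory:
    """Per-cycle state occupancy, utility accrual and costing events.

    ``occupancy[t - 1]`` is the distribution during month ``t`` for
    ``t = 1..horizon``; ``end_state`` is the distribution after the full
    horizon (the two-year outcome).  Event arrays are aligned the same
    way and hold cohort fractions: chemotherapy course starts per line,
    response evaluations per line, and entries into palliative care.
    """

    space: StateSpace
    occupancy: np.ndarray  # (horizon, n)
    end_state: np.ndarray
    course_starts_first: np.ndarray
    course_starts_second: np.ndarray
    evaluations_first: np.ndarray
    evaluations_second: np.ndarray
    palliative_entries: np.ndarray

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0]

    def state_occupancy(self, state: str) -> np.ndarray:
        mask = np.array([c.state == state for c in self.space.compartments])
        return self.occupancy[:, mask].sum(axis=1)

    def end_state_probabilities(self) -> dict[str, float]:
        out = {s: 0.0 for s in ("CR", "PR", "SD", "PD", "DEAD")}
        for comp, p in zip(self.space.compartments, self.end_state):
            out[comp.state] += float(p)
        return out

    def to_frame(self, utilities: UtilitySet):
        """Trajectory as a tidy DataFrame (cycle, compartment, occupancy,
        utility_accrual) for export."""
        import pandas as pd

        u = utilities.by_state()
        rows = [
            {
                "cycle": t + 1,
                "compartment": comp.name,
                "occupancy": float(self.occupancy[t, j]),
                "utility_accrual": float(self.occupancy[t, j]) * u[comp.state] / 12.0,
            }
            for t in range(self.horizon)
            for j, comp in enumerate(self.space.compartments)
        ]
        return pd.DataFrame(rows)


def run_cohort(
    params: ModelParameters,
    strategy: str,
    include_second_line: bool = True,
    space: StateSpace | None = None,
) -> CohortTrajectory:
    """Propagate the cohort over the two-year horizon.

    With ``include_second_line`` off, first-line failures and relapses go
    directly to palliative care (the no-second-line scenario).
    """
    if space is None:
        space = build_state_space(params, strategy, include_second_line)
    horizon = params.constants.horizon_cycles
    n = space.n
    occ = np.zeros((horizon, n))
    occ[0] = space.initial_occupancy()

    pd2_entry = (
        space.index.get("PD2_c1") if space.include_second_line else None
    )
    course2 = np.zeros(horizon)
    pall_in = np.zeros(horizon)
    if pd2_entry is not None:
        course2[0] = occ[0, pd2_entry]
    pall_in[0] = occ[0, space.palliative]

    prev = occ[0]
    for t in range(2, horizon + 1):
        survive = _survival_factors(space, params, t)
        alive = prev * survive
        cur = space.movement @ alive
        cur[space.dead] += (prev - alive).sum()
        if abs(cur.sum() - prev.sum()) > MASS_TOL:
            raise AssertionError(f"mass not conserved at cycle {t}")
        occ[t - 1] = cur
        if pd2_entry is not None:
            course2[t - 1] = cur[pd2_entry]
        pall_in[t - 1] = cur[space.palliative] - alive[space.palliative]
        prev = cur

    end_state = transition_step(prev, horizon + 1, space, params)

    course1 = np.zeros(horizon)
    course1[0] = 1.0
    eval1 = occ[:, space.index[f"PD1_c{params.constants.first_line_switch_cycle}"]]
    if pd2_entry is not None:
        eval2 = occ[
            :, space.index[f"PD2_c{params.constants.second_line_eval_cycles}"]
        ].copy()
    else:
        eval2 = np.zeros(horizon)

    return CohortTrajectory(
        space=space,
        occupancy=occ,
        end_state=end_state,
        course_starts_first=course1,
        course_starts_second=course2,
        evaluations_first=eval1.copy(),
        evaluations_second=eval2,
        palliative_entries=pall_in,
    )


def discount_factors(constants: ModelConstants) -> np.ndarray:
    """Per-cycle discount factors: year-1 flows undiscounted, year-2 flows
    divided by (1 + rate) as a single annual step."""
    horizon = constants.horizon_cycles
    f = np.ones(horizon)
    f[12:] = 1.0 / (1.0 + constants.discount_rate)
    return f


def compute_qalys(
    traj: CohortTrajectory,
    utilities: UtilitySet,
    constants: ModelConstants,
) -> float:
    """Discounted QALYs over the horizon.

    Each month contributes occupancy-weighted state utility / 12; cycles
    13-24 are discounted by 1/(1+r).  No half-cycle correction.
    """
    u = utilities.by_state()
    u_vec = np.array([u[c.state] for c in traj.space.compartments])
    per_cycle = traj.occupancy @ u_vec / 12.0
    return float(per_cycle @ discount_factors(constants))
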