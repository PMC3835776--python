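"""Synthetic inputs and a patient-level microsimulation oracle.

The published model inputs do not include tabulated survival curves or a
national life table, so this module generates the stand-ins the rest of
the package consumes: noisy survival anchor points with a known true
hazard (for calibration-recovery testing), a parametric synthetic life
table, and randomly perturbed — but always valid — parameter packs.  It
also provides an independent patient-level microsimulation of the same
disease pathway, used to validate the deterministic cohort engine: both
apply death before movement within a cycle, so cohort occupancy is the
exact expectation of the microsimulated paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .costing import cost_structure
from .engine import StateSpace, build_state_space, discount_factors, _survival_factors
from .parameters import ModelParameters, UnitCostTable
from .survival import LifeTable, SurvivalPoint

__all__ = [
    "SyntheticSpec",
    "generate_survival_points",
    "generate_life_table",
    "generate_parameter_pack",
    "MicrosimResult",
    "microsim_oracle",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs for the synthetic generators.

    ``true_hazards`` maps (regimen, line) to the monthly cancer hazard
    from which survival points are simulated; ``noise_sigma`` is the
    additive Gaussian noise on the survival scale; ``life_base`` and
    ``life_growth`` parameterise the synthetic life table (annual
    mortality ``base * growth**(age - 65)``); ``perturbation`` scales the
    log-normal jitter used for random parameter packs.
    """

    seed: int = 0
    true_hazards: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sigma: float = 0.02
    n_points: int = 24
    life_base: float = 0.02
    life_growth: float = 1.1
    perturbation: float = 0.1

    def __post_init__(self) -> None:
        for key, rate in self.true_hazards.items():
            if rate <= 0:
                raise ValueError(f"hazard for {key} must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


def generate_survival_points(
    rate: float,
    times: Sequence[float],
    sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[SurvivalPoint]:
    """Survival anchor points from an exponential curve with known hazard.

    ``S(t) = exp(-rate * t)`` plus additive Gaussian noise, clipped into
    (0, 1] and monotonised by a running minimum so the series is a valid
    survival curve.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    s = np.exp(-rate * t)
    if sigma > 0:
        s = s + rng.normal(0.0, sigma, size=t.shape)
    s = np.clip(s, 1e-6, 1.0)
    s = np.minimum.accumulate(s)
    return [SurvivalPoint(float(ti), float(si)) for ti, si in zip(t, s)]


def generate_life_table(
    base_annual_rate: float,
    growth: float = 1.0,
    ages: Sequence[int] = range(65, 91),
) -> LifeTable:
    """Synthetic all-cause life table: geometric growth from the base age.

    ``q(age) = min(base * growth**(age - ages[0]), 1)``.
    """
    if not (0.0 < base_annual_rate < 1.0):
        raise ValueError("base rate must lie in (0, 1)")
    if growth < 1.0:
        raise ValueError("growth must be >= 1")
    ages = tuple(int(a) for a in ages)
    rates = tuple(
        min(base_annual_rate * growth ** (a - ages[0]), 1.0) for a in ages
    )
    table = LifeTable(ages=ages, annual_mortality=rates)
    table.validate()
    return table


def _jitter(rng: np.random.Generator, value: float, scale: float) -> float:
    if value <= 0 or scale <= 0:
        return value
    return float(value * rng.lognormal(0.0, scale))


def generate_parameter_pack(
    base: ModelParameters, seed: int = 0, perturbation: float = 0.1
) -> ModelParameters:
    """A random valid parameter pack perturbed around a base pack.

    Efficacy simplexes are jittered multiplicatively and renormalised;
    durations, unit costs, vial prices and cancer hazards get log-normal
    jitter.  Utilities and model constants are left at base so every
    invariant (ordering, horizon) holds by construction.  With
    ``perturbation == 0`` the result equals the base pack.
    """
    if perturbation <= 0:
        return base
    rng = np.random.default_rng(seed)
    eff = {}
    for key in sorted(base.efficacy):
        p = base.efficacy[key]
        probs = np.array([_jitter(rng, v, perturbation) for v in p.probs])
        total = probs.sum()
        if total <= 0:
            probs, total = np.array(p.probs), sum(p.probs)
        probs = probs / total
        eff[key] = replace(
            p,
            p_cr=float(probs[0]),
            p_pr=float(probs[1]),
            p_sd=float(probs[2]),
            p_pd=float(probs[3]),
            dur_cr=_jitter(rng, p.dur_cr, perturbation),
            dur_pr=_jitter(rng, p.dur_pr, perturbation),
            dur_sd=_jitter(rng, p.dur_sd, perturbation),
        )
    costs = UnitCostTable(
        entries={
            k: _jitter(rng, v, perturbation)
            for k, v in sorted(base.costs.entries.items())
        },
        units=dict(base.costs.units),
        vials={
            drug: tuple(
                (strength, _jitter(rng, cost, perturbation))
                for strength, cost in strengths
            )
            for drug, strengths in sorted(base.costs.vials.items())
        },
    )
    hazards = {
        key: _jitter(rng, rate, perturbation)
        for key, rate in sorted(base.hazards.items())
    }
    out = ModelParameters(
        country=base.country,
        regimens=base.regimens,
        efficacy=eff,
        toxicity=base.toxicity,
        mixes=base.mixes,
        costs=costs,
        utilities=base.utilities,
        resource=base.resource,
        constants=base.constants,
        hazards=hazards,
        life_table=base.life_table,
    )
    out.validate()
    return out


@dataclass(frozen=True)
class MicrosimResult:
    """Monte-Carlo estimates of per-patient discounted cost and QALYs."""

    n: int
    cost_mean: float
    cost_se: float
    qaly_mean: float
    qaly_se: float


def microsim_oracle(
    params: ModelParameters,
    strategy: str,
    n: int = 20_000,
    seed: int = 0,
    include_second_line: bool = True,
    space: StateSpace | None = None,
) -> MicrosimResult:
    """Patient-level simulation of the cohort model's pathway.

    Each patient walks the same tunnel-expanded state space with the same
    event ordering as the cohort engine (death first, then movement among
    survivors), accruing the same per-compartment costs and utilities, so
    the cohort results are the exact expectations of these paths.
    Returns means with Monte-Carlo standard errors.
    """
    if n < 1:
        raise ValueError("need at least one patient")
    rng = np.random.default_rng(seed)
    if space is None:
        space = build_state_space(params, strategy, include_second_line)
    horizon = params.constants.horizon_cycles
    nn = space.n

    # successor sampling tables (padded cumulative distributions)
    max_succ = max(len(c.successors) for c in space.compartments)
    succ_idx = np.zeros((nn, max_succ), dtype=np.int64)
    succ_cum = np.ones((nn, max_succ))
    for j, comp in enumerate(space.compartments):
        cum = 0.0
        for k, (idx, p) in enumerate(comp.successors):
            cum += p
            succ_idx[j, k] = idx
            succ_cum[j, k] = cum
        succ_idx[j, len(comp.successors):] = comp.successors[-1][0]

    structure = cost_structure(space, params, strategy)
    c_vec = structure.per_cycle_total
    u = params.utilities.by_state()
    u_vec = np.array([u[c.state] for c in space.compartments]) / 12.0
    disc = discount_factors(params.constants)

    state = np.full(n, space.entry, dtype=np.int64)
    cost = np.full(n, c_vec[space.entry] * disc[0])
    qaly = np.full(n, u_vec[space.entry] * disc[0])
    if space.entry == space.palliative:  # degenerate space
        cost += structure.palliative_entry_cost * disc[0]

    for t in range(2, horizon + 1):
        survive = _survival_factors(space, params, t)
        alive = state != space.dead
        dies = rng.random(n) > survive[state]
        # movement among survivors
        movers = alive & ~dies
        u01 = rng.random(n)
        k = (u01[:, None] > succ_cum[state]).sum(axis=1)
        nxt = succ_idx[state, k]
        new_state = state.copy()
        new_state[alive & dies] = space.dead
        new_state[movers] = nxt[movers]
        entered_pall = (new_state == space.palliative) & (state != space.palliative)
        state = new_state
        d = disc[t - 1]
        cost += c_vec[state] * d
        cost[entered_pall] += structure.palliative_entry_cost * d
        qaly += u_vec[state] * d

    return MicrosimResult(
        n=n,
        cost_mean=float(cost.mean()),
        cost_se=float(cost.std(ddof=1) / np.sqrt(n)),
        qaly_mean=float(qaly.mean()),
        qaly_se=float(qaly.std(ddof=1) / np.sqrt(n)),
    )
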