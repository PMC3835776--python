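"""Probabilistic and deterministic sensitivity analysis.

The probabilistic analysis (PSA) redraws every uncertain input feeding
the two modelled strategies — response probabilities, utilities, toxicity
probabilities, second-line mixes, response durations, unit costs and
resource-use quantities — and reruns both strategies per iteration.
Probabilities and utilities are drawn from beta distributions and costs
and resource quantities from gamma distributions, both parameterised by
method of moments from the point estimate with a default standard error
of 20% of the mean (no dispersion is published, so a conventional spread
is used; it is overridable per analysis).  The four response
probabilities are drawn independently and renormalised to the simplex.
Cancer-mortality hazards are calibration outputs rather than sampled
inputs and are held fixed.

Each iteration uses its own random stream derived from (master seed,
iteration index), so results are reproducible and independent of
execution order.

The deterministic analysis (DSA) moves one parameter at a time to 20%
below and above base case and reports the incremental result at each
bound, ordered by ICER range width (tornado order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .cea import (
    CEAResult,
    COMPARATOR_STRATEGY,
    REFERENCE_STRATEGY,
    compare_strategies,
)
from .parameters import (
    ModelParameters,
    ParameterError,
    SecondLineMix,
    UnitCostTable,
    UtilitySet,
)

__all__ = [
    "PSAConfig",
    "PSASampleSet",
    "CEACCurve",
    "beta_from_moments",
    "gamma_from_moments",
    "sample_beta",
    "sample_gamma",
    "run_psa",
    "ceac",
    "DSAScenario",
    "DSAResult",
    "apply_override",
    "default_dsa_scenarios",
    "run_dsa",
]


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta parameters (alpha, beta) for a probability.

    Requires ``0 < mean < 1`` and ``se**2 < mean * (1 - mean)``; a zero
    standard error denotes a point mass and is rejected here (samplers
    handle it by returning the mean).
    """
    if not (0.0 < mean < 1.0):
        raise ValueError(f"mean {mean} outside (0, 1)")
    if se <= 0:
        raise ValueError("se must be positive; se == 0 is a point mass")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ValueError(f"se {se} too large for a beta with mean {mean}")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma parameters (shape, scale): shape*scale = mean."""
    if mean <= 0 or se <= 0:
        raise ValueError("mean and se must be positive")
    return (mean / se) ** 2, se * se / mean


def sample_beta(rng: np.random.Generator, mean: float, se: float) -> float:
    """One beta draw; degenerate means (0, 1) and se = 0 are point masses.

    When the requested spread is infeasible for a beta (mean close to 1),
    the standard error is shrunk to the largest feasible value.
    """
    if se <= 0 or mean <= 0.0 or mean >= 1.0:
        return mean
    cap = 0.99 * math.sqrt(mean * (1.0 - mean))
    a, b = beta_from_moments(mean, min(se, cap))
    return float(rng.beta(a, b))


def sample_gamma(rng: np.random.Generator, mean: float, se: float) -> float:
    """One gamma draw; non-positive mean or se is a point mass."""
    if mean <= 0 or se <= 0:
        return mean
    shape, scale = gamma_from_moments(mean, se)
    return float(rng.gamma(shape, scale))


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSAConfig:
    """PSA settings: iteration count, master seed and dispersion rule."""

    iterations: int = 10_000
    seed: int = 0
    dispersion: float = 0.20  # SE as a fraction of the mean

    def __post_init__(self) -> None:
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass
class PSASampleSet:
    """Per-iteration incremental results (reference minus comparator)."""

    config: PSAConfig
    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    sampled_utilities: np.ndarray  # (iterations, 4): CR, PR, SD, PD

    def __len__(self) -> int:
        return len(self.delta_cost)

    def quadrant_counts(self) -> dict[str, int]:
        dc, dq = self.delta_cost, self.delta_qalys
        return {
            "dominant": int(np.sum((dc < 0) & (dq > 0))),
            "dominated": int(np.sum((dc > 0) & (dq < 0))),
            "trade-off NE": int(np.sum((dc >= 0) & (dq >= 0)) - np.sum((dc == 0) & (dq == 0))),
            "trade-off SW": int(np.sum((dc <= 0) & (dq <= 0)) - np.sum((dc == 0) & (dq == 0))),
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(len(self), dtype=int),
                "delta_cost": self.delta_cost,
                "delta_qalys": self.delta_qalys,
            }
        )


def _sample_simplex(
    rng: np.random.Generator, probs: Sequence[float], dispersion: float
) -> np.ndarray:
    draws = np.array([sample_beta(rng, p, dispersion * p) for p in probs])
    total = draws.sum()
    if total <= 0:
        return np.asarray(probs, dtype=float)
    return draws / total


def _reachable_regimens(params: ModelParameters) -> list[tuple[str, str]]:
    keys = [(REFERENCE_STRATEGY, "first"), (COMPARATOR_STRATEGY, "first")]
    for fl in (REFERENCE_STRATEGY, COMPARATOR_STRATEGY):
        for name in params.active_second_line(fl):
            key = (name, "second")
            if key not in keys:
                keys.append(key)
    return keys


def sample_parameters(
    params: ModelParameters, rng: np.random.Generator, dispersion: float
) -> ModelParameters:
    """One PSA redraw of every uncertain input reaching the two strategies."""
    if dispersion <= 0:
        return params
    d = dispersion
    reachable = _reachable_regimens(params)

    efficacy = dict(params.efficacy)
    toxicity = dict(params.toxicity)
    for key in reachable:
        p = params.efficacy[key]
        probs = _sample_simplex(rng, p.probs, d)
        efficacy[key] = replace(
            p,
            p_cr=float(probs[0]),
            p_pr=float(probs[1]),
            p_sd=float(probs[2]),
            p_pd=float(probs[3]),
            dur_cr=sample_gamma(rng, p.dur_cr, d * p.dur_cr),
            dur_pr=sample_gamma(rng, p.dur_pr, d * p.dur_pr),
            dur_sd=sample_gamma(rng, p.dur_sd, d * p.dur_sd),
        )
        t = params.toxicity[key]
        toxicity[key] = replace(
            t,
            p_neutropenia=sample_beta(rng, t.p_neutropenia, d * t.p_neutropenia),
            p_febrile_neutropenia=sample_beta(
                rng, t.p_febrile_neutropenia, d * t.p_febrile_neutropenia
            ),
            p_thrombocytopenia=sample_beta(
                rng, t.p_thrombocytopenia, d * t.p_thrombocytopenia
            ),
            p_anaemia=sample_beta(rng, t.p_anaemia, d * t.p_anaemia),
        )

    mixes = {}
    for fl, mix in params.mixes.items():
        names = sorted(mix.entries)
        weights = _sample_simplex(rng, [mix.entries[n] for n in names], d)
        mixes[fl] = SecondLineMix(
            country=mix.country,
            first_line=fl,
            entries=dict(zip(names, map(float, weights))),
        )

    u = params.utilities
    utilities = UtilitySet(
        u_cr=sample_beta(rng, u.u_cr, d * u.u_cr),
        u_pr=sample_beta(rng, u.u_pr, d * u.u_pr),
        u_sd=sample_beta(rng, u.u_sd, d * u.u_sd),
        u_pd=sample_beta(rng, u.u_pd, d * u.u_pd),
    )

    costs = UnitCostTable(
        entries={
            k: sample_gamma(rng, v, d * v)
            for k, v in sorted(params.costs.entries.items())
        },
        units=dict(params.costs.units),
        vials={
            drug: tuple(
                (strength, sample_gamma(rng, cost, d * cost))
                for strength, cost in strengths
            )
            for drug, strengths in sorted(params.costs.vials.items())
        },
    )

    res = params.resource

    def qmap(mapping, clip1=False):
        out = {}
        for k, v in mapping.items():
            s = sample_gamma(rng, v, d * v)
            out[k] = min(s, 1.0) if clip1 else s
        return out

    resource = replace(
        res,
        diagnosis_visits=qmap(res.diagnosis_visits),
        diagnosis_tests=qmap(res.diagnosis_tests, clip1=True),
        evaluation_tests=qmap(res.evaluation_tests, clip1=True),
        per_cycle_tests=qmap(res.per_cycle_tests, clip1=True),
        followup_tests=qmap(res.followup_tests, clip1=True),
        followup_visits=qmap(res.followup_visits),
        premedication=tuple(
            replace(
                item,
                quantity=sample_gamma(rng, item.quantity, d * item.quantity),
                proportion=min(
                    sample_gamma(rng, item.proportion, d * item.proportion), 1.0
                ),
            )
            for item in res.premedication
        ),
        gcsf=replace(
            res.gcsf,
            uptake=tuple(
                (cond, min(sample_gamma(rng, p, d * p), 1.0))
                for cond, p in res.gcsf.uptake
            ),
        ),
        dose_reduction=replace(
            res.dose_reduction,
            uptake=min(
                sample_gamma(
                    rng, res.dose_reduction.uptake, d * res.dose_reduction.uptake
                ),
                1.0,
            ),
            magnitude=min(
                sample_gamma(
                    rng,
                    res.dose_reduction.magnitude,
                    d * res.dose_reduction.magnitude,
                ),
                1.0,
            ),
        ),
    )

    regimens = {}
    for name, reg in params.regimens.items():
        regimens[name] = replace(
            reg,
            admission_days=sample_gamma(rng, reg.admission_days, d * reg.admission_days),
            outpatient_attendances=sample_gamma(
                rng, reg.outpatient_attendances, d * reg.outpatient_attendances
            ),
        )

    return ModelParameters(
        country=params.country,
        regimens=regimens,
        efficacy=efficacy,
        toxicity=toxicity,
        mixes=mixes,
        costs=costs,
        utilities=utilities,
        resource=resource,
        constants=params.constants,
        hazards=params.hazards,
        life_table=params.life_table,
    )


def run_psa(
    params: ModelParameters,
    config: PSAConfig | None = None,
    reference: str = REFERENCE_STRATEGY,
    comparator: str = COMPARATOR_STRATEGY,
) -> PSASampleSet:
    """Monte-Carlo PSA: redraw all inputs, rerun both strategies, record
    the incremental cost and QALY pair per iteration.

    Iteration ``i`` draws from ``default_rng([seed, i])``, so a fixed
    seed reproduces the sample set exactly regardless of iteration order.
    """
    config = config or PSAConfig(iterations=params.constants.psa_iterations)
    it = config.iterations
    delta_cost = np.empty(it)
    delta_qalys = np.empty(it)
    sampled_u = np.empty((it, 4))
    for i in range(it):
        rng = np.random.default_rng([config.seed, i])
        sampled = sample_parameters(params, rng, config.dispersion)
        _, _, cea = compare_strategies(sampled, reference, comparator)
        delta_cost[i] = cea.delta_cost
        delta_qalys[i] = cea.delta_qalys
        u = sampled.utilities
        sampled_u[i] = (u.u_cr, u.u_pr, u.u_sd, u.u_pd)
    return PSASampleSet(
        config=config,
        delta_cost=delta_cost,
        delta_qalys=delta_qalys,
        sampled_utilities=sampled_u,
    )


@dataclass(frozen=True)
class CEACCurve:
    """Probability the reference strategy is cost-effective per threshold."""

    thresholds: tuple[float, ...]
    probabilities: tuple[float, ...]

    def at(self, threshold: float) -> float:
        try:
            return self.probabilities[self.thresholds.index(threshold)]
        except ValueError:
            raise KeyError(f"threshold {threshold} not on the curve") from None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"threshold": self.thresholds, "probability": self.probabilities}
        )


def ceac(
    samples: PSASampleSet, thresholds: Sequence[float] | None = None
) -> CEACCurve:
    """Cost-effectiveness acceptability curve from PSA samples.

    At willingness-to-pay ``t`` the probability is the fraction of
    iterations with positive net monetary benefit
    ``t * dQALY - dCost > 0``.
    """
    if len(samples) == 0:
        raise ValueError("empty sample set")
    if thresholds is None:
        thresholds = tuple(range(0, 105_000, 5_000))
    probs = []
    for t in thresholds:
        nmb = t * samples.delta_qalys - samples.delta_cost
        probs.append(float(np.mean(nmb > 0)))
    return CEACCurve(
        thresholds=tuple(float(t) for t in thresholds),
        probabilities=tuple(probs),
    )


# ---------------------------------------------------------------------------
# deterministic (one-way) sensitivity analysis
# ---------------------------------------------------------------------------

_EFF_FIELDS = ("p_cr", "p_pr", "p_sd", "p_pd")


def _override_efficacy_prob(profile, fld: str, value: float):
    value = min(max(value, 0.0), 1.0)
    others = [f for f in _EFF_FIELDS if f != fld]
    rest = sum(getattr(profile, f) for f in others)
    if rest <= 0:
        raise ParameterError("cannot rebalance a degenerate probability row")
    scale = (1.0 - value) / rest
    kwargs = {fld: value}
    kwargs.update({f: getattr(profile, f) * scale for f in others})
    return replace(profile, **kwargs)


def _resolve(params: ModelParameters, path: str) -> tuple[float, Callable[[float], ModelParameters]]:
    """Return (base value, setter) for a dotted parameter path.

    Path families: ``utilities.<state>``,
    ``efficacy.<regimen>.<line>.<field>`` (probability overrides
    rebalance the rest of the simplex proportionally),
    ``toxicity.<regimen>.<line>.<field>``, ``mix.<first>.<second>``
    (other mix entries rebalance), ``cost.<key>``, ``vial.<drug>``
    (all strengths scale with the first), ``cost_scale.<group>`` (a
    multiplier over a named group of cost keys, base 1.0),
    ``regimen.<name>.admission_days`` and ``hazard.<regimen>.<line>``.
    """
    parts = path.split(".")
    family = parts[0]

    if family == "utilities":
        state = parts[1]
        attr = f"u_{state}"
        base = getattr(params.utilities, attr)

        def set_util(v: float) -> ModelParameters:
            return replace_params(params, utilities=replace(params.utilities, **{attr: v}))

        return base, set_util

    if family in ("efficacy", "toxicity"):
        _, reg, line, fld = parts
        table = params.efficacy if family == "efficacy" else params.toxicity
        profile = table[(reg, line)]
        base = getattr(profile, fld)

        def set_prof(v: float) -> ModelParameters:
            if family == "efficacy" and fld in _EFF_FIELDS:
                new = _override_efficacy_prob(profile, fld, v)
            else:
                new = replace(profile, **{fld: v})
            updated = dict(table)
            updated[(reg, line)] = new
            key = "efficacy" if family == "efficacy" else "toxicity"
            return replace_params(params, **{key: updated})

        return base, set_prof

    if family == "mix":
        _, fl, sl = parts
        mix = params.mix_for(fl)
        base = mix.entries.get(sl, 0.0)

        def set_mix(v: float) -> ModelParameters:
            v = min(max(v, 0.0), 1.0)
            others = {n: w for n, w in mix.entries.items() if n != sl}
            rest = sum(others.values())
            scale = (1.0 - v) / rest if rest > 0 else 0.0
            entries = {n: w * scale for n, w in others.items()}
            entries[sl] = v
            mixes = dict(params.mixes)
            mixes[fl] = SecondLineMix(country=mix.country, first_line=fl, entries=entries)
            return replace_params(params, mixes=mixes)

        return base, set_mix

    if family == "cost":
        key = parts[1]
        base = params.costs.get(key)

        def set_cost(v: float) -> ModelParameters:
            entries = dict(params.costs.entries)
            entries[key] = v
            return replace_params(
                params, costs=replace(params.costs, entries=entries)
            )

        return base, set_cost

    if family == "vial":
        drug = parts[1]
        strengths = params.costs.vials[drug]
        base = strengths[0][1]

        def set_vial(v: float) -> ModelParameters:
            factor = v / base if base else 0.0
            vials = dict(params.costs.vials)
            vials[drug] = tuple((s, c * factor) for s, c in strengths)
            return replace_params(params, costs=replace(params.costs, vials=vials))

        return base, set_vial

    if family == "cost_scale":
        group = parts[1]
        if group == "toxicity_management":
            keys = [
                "manage_neutropenia",
                "manage_febrile_neutropenia",
                "manage_thrombocytopenia",
                "manage_anaemia",
            ]
        elif group == "premedication":
            keys = sorted(
                {item.cost_key for item in params.resource.premedication}
                | {params.resource.gcsf.cost_key}
            )
        else:
            raise ParameterError(f"unknown cost group {group!r}")

        def set_scale(v: float) -> ModelParameters:
            entries = dict(params.costs.entries)
            for k in keys:
                if k in entries:
                    entries[k] = entries[k] * v
            return replace_params(
                params, costs=replace(params.costs, entries=entries)
            )

        return 1.0, set_scale

    if family == "regimen":
        _, name, fld = parts
        reg = params.regimens[name]
        base = getattr(reg, fld)

        def set_reg(v: float) -> ModelParameters:
            regimens = dict(params.regimens)
            regimens[name] = replace(reg, **{fld: v})
            return replace_params(params, regimens=regimens)

        return base, set_reg

    if family == "hazard":
        _, reg, line = parts
        base = params.hazards[(reg, line)]

        def set_haz(v: float) -> ModelParameters:
            hazards = dict(params.hazards)
            hazards[(reg, line)] = v
            return replace_params(params, hazards=hazards)

        return base, set_haz

    raise ParameterError(f"unknown parameter path {path!r}")


def replace_params(params: ModelParameters, **kwargs) -> ModelParameters:
    """Shallow-copy a :class:`ModelParameters` with fields replaced."""
    fields = dict(
        country=params.country,
        regimens=params.regimens,
        efficacy=params.efficacy,
        toxicity=params.toxicity,
        mixes=params.mixes,
        costs=params.costs,
        utilities=params.utilities,
        resource=params.resource,
        constants=params.constants,
        hazards=params.hazards,
        life_table=params.life_table,
    )
    fields.update(kwargs)
    return ModelParameters(**fields)


def apply_override(params: ModelParameters, path: str, value: float) -> ModelParameters:
    """Return a copy of ``params`` with one addressed parameter overridden."""
    _, setter = _resolve(params, path)
    return setter(value)


@dataclass(frozen=True)
class DSAScenario:
    """One one-way scenario: a parameter path varied to +/- the fraction."""

    name: str
    path: str
    fraction: float = 0.20

    def bounds(self, params: ModelParameters) -> tuple[float, float, float]:
        base, _ = _resolve(params, self.path)
        return base, base * (1.0 - self.fraction), base * (1.0 + self.fraction)


@dataclass
class DSAResult:
    """Incremental results at the low/high bound of one scenario."""

    scenario: DSAScenario
    base: float
    low: float
    high: float
    cea_low: CEAResult
    cea_high: CEAResult

    @property
    def icer_range(self) -> float:
        """Width of the ICER span across the bounds (tornado ordering)."""
        icers = [
            c.icer for c in (self.cea_low, self.cea_high) if c.icer is not None
        ]
        if len(icers) < 2:
            return math.inf
        return abs(icers[0] - icers[1])

    @property
    def effect(self) -> str:
        quads = {self.cea_low.quadrant, self.cea_high.quadrant}
        if quads == {"dominant"}:
            return "reference remains dominant"
        return " / ".join(sorted(quads))


def default_dsa_scenarios(fraction: float = 0.20) -> list[DSAScenario]:
    """The standard one-way scenario battery for the base-case comparison."""
    mk = lambda name, path: DSAScenario(name=name, path=path, fraction=fraction)
    return [
        mk("PR duration, first-line doxorubicin/ifosfamide",
           "efficacy.doxorubicin_ifosfamide.first.dur_pr"),
        mk("SD duration, first-line doxorubicin/ifosfamide",
           "efficacy.doxorubicin_ifosfamide.first.dur_sd"),
        mk("PR duration, first-line trabectedin", "efficacy.trabectedin.first.dur_pr"),
        mk("SD duration, first-line trabectedin", "efficacy.trabectedin.first.dur_sd"),
        mk("P(SD), first-line doxorubicin/ifosfamide",
           "efficacy.doxorubicin_ifosfamide.first.p_sd"),
        mk("P(SD), first-line trabectedin", "efficacy.trabectedin.first.p_sd"),
        mk("P(SD), second-line trabectedin", "efficacy.trabectedin.second.p_sd"),
        mk("P(second-line trabectedin after doxorubicin/ifosfamide)",
           "mix.doxorubicin_ifosfamide.trabectedin"),
        mk("Admission days, doxorubicin/ifosfamide infusion",
           "regimen.doxorubicin_ifosfamide.admission_days"),
        mk("Unit cost of doxorubicin", "vial.doxorubicin"),
        mk("Unit cost of ifosfamide", "vial.ifosfamide"),
        mk("Unit cost of trabectedin", "vial.trabectedin"),
        mk("Cost of managing adverse events", "cost_scale.toxicity_management"),
        mk("Cost of pre/post-chemotherapy medications", "cost_scale.premedication"),
        mk("Cost of palliative care", "cost.palliative_care"),
        mk("Utility for progressive disease", "utilities.pd"),
        mk("Utility for stable disease", "utilities.sd"),
    ]


def run_dsa(
    params: ModelParameters,
    scenarios: Sequence[DSAScenario] | None = None,
    reference: str = REFERENCE_STRATEGY,
    comparator: str = COMPARATOR_STRATEGY,
) -> list[DSAResult]:
    """One-way DSA over the scenario battery, in tornado (range) order."""
    if scenarios is None:
        scenarios = default_dsa_scenarios(params.constants.dsa_fraction)
    results = []
    for sc in scenarios:
        base, low, high = sc.bounds(params)
        _, _, cea_low = compare_strategies(
            apply_override(params, sc.path, low), reference, comparator
        )
        _, _, cea_high = compare_strategies(
            apply_override(params, sc.path, high), reference, comparator
        )
        results.append(
            DSAResult(
                scenario=sc, base=base, low=low, high=high,
                cea_low=cea_low, cea_high=cea_high,
            )
        )
    # widest ICER span first; scenarios with an undefined ICER at a bound last
    results.sort(
        key=lambda r: (math.isinf(r.icer_range),
                       -r.icer_range if math.isfinite(r.icer_range) else 0.0)
    )
    return results
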