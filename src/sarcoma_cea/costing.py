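"""Per-cycle costing and two-year cost aggregation.

Costs are attributed to the ten reporting categories used for the
two-year cost breakdown: diagnosis, first-line cytotoxics, second-line
cytotoxics, evaluations of response, hospitalisations for chemotherapy
infusion, outpatient attendances for chemotherapy, tests before each
cycle, pre-/post-chemotherapy medication, palliative care, and management
of haematological toxicity.

Drug acquisition uses whole-vial dispensing with wastage at a fixed body
surface area (default 1.8 m2): the dispensed vial combination is the
cheapest integer combination of the country's available vial strengths
covering the required dose.  Regimens containing ifosfamide also receive
mesna dosed at the ifosfamide dose.  Expected dose reduction late in a
course is applied as an acquisition-cost multiplier.  Second-line
quantities are probability-weighted over the country's second-line mix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .engine import CohortTrajectory, StateSpace, discount_factors, second_line_aggregate
from .parameters import (
    ModelParameters,
    ParameterError,
    Regimen,
    ResourceUseProfile,
    ToxicityProfile,
    UnitCostTable,
)

__all__ = [
    "CATEGORIES",
    "CATEGORY_LABELS",
    "CostBreakdown",
    "DrugOrder",
    "cheapest_vial_combination",
    "drug_acquisition_cost",
    "supportive_medication_cost",
    "expected_toxicity_cost",
    "treatment_cycle_cost",
    "per_course_test_cost",
    "diagnosis_cost",
    "evaluation_event_cost",
    "followup_monthly_cost",
    "cycle_cost",
    "CostStructure",
    "cost_structure",
    "aggregate_costs",
]

CATEGORIES = (
    "diagnosis",
    "first_line_cytotoxics",
    "second_line_cytotoxics",
    "evaluations",
    "hospitalisation",
    "outpatient",
    "cycle_tests",
    "premedication",
    "palliative_care",
    "toxicity_management",
)

CATEGORY_LABELS = {
    "diagnosis": "Diagnosis",
    "first_line_cytotoxics": "First-line cytotoxics",
    "second_line_cytotoxics": "Second-line cytotoxics",
    "evaluations": "Evaluations of response",
    "hospitalisation": "Hospitalisations for chemotherapy infusion",
    "outpatient": "Outpatient attendances for chemotherapy",
    "cycle_tests": "Tests before each cycle of chemotherapy",
    "premedication": "Pre- and postchemotherapy medication",
    "palliative_care": "Palliative care",
    "toxicity_management": "Management of haematological toxicity",
}


@dataclass
class CostBreakdown:
    """Amounts by reporting category; the total is always the exact sum."""

    amounts: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CATEGORIES}
    )

    @property
    def total(self) -> float:
        return sum(self.amounts.values())

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            {c: self.amounts[c] + other.amounts[c] for c in CATEGORIES}
        )

    def scaled(self, factor: float) -> "CostBreakdown":
        return CostBreakdown({c: v * factor for c, v in self.amounts.items()})

    def validate(self) -> None:
        for cat, v in self.amounts.items():
            if v < -1e-9:
                raise ParameterError(f"negative cost in category {cat}")


@dataclass(frozen=True)
class DrugOrder:
    """Whole-vial dispensing record for one drug in one cycle."""

    drug: str
    required_mg: float
    vials: tuple[tuple[float, int], ...]  # (strength_mg, count)
    cost: float

    @property
    def dispensed_mg(self) -> float:
        return sum(strength * count for strength, count in self.vials)


def cheapest_vial_combination(
    required_mg: float, strengths: Iterable[tuple[float, float]]
) -> tuple[tuple[tuple[float, int], ...], float]:
    """Cheapest integer vial combination covering ``required_mg``.

    ``strengths`` is a list of (strength_mg, cost_per_vial).  With a
    single strength this is the ceiling of dose over strength; with
    several, all integer combinations up to the single-strength ceilings
    are searched (catalogues carry at most a few strengths per drug).
    """
    strengths = sorted(strengths, reverse=True)
    if not strengths:
        raise ParameterError("no vial strengths available")
    if required_mg <= 0:
        return ((), 0.0)

    best: tuple[float, tuple[tuple[float, int], ...]] | None = None

    def search(i: int, remaining: float, cost: float, picked: list[tuple[float, int]]):
        nonlocal best
        if best is not None and cost >= best[0]:
            return
        strength, unit_cost = strengths[i]
        if i == len(strengths) - 1:
            count = max(int(math.ceil(remaining / strength - 1e-12)), 0)
            total = cost + count * unit_cost
            if best is None or total < best[0]:
                combo = picked + ([(strength, count)] if count else [])
                best = (total, tuple(combo))
            return
        max_count = max(int(math.ceil(remaining / strength - 1e-12)), 0)
        for count in range(max_count + 1):
            search(
                i + 1,
                remaining - count * strength,
                cost + count * unit_cost,
                picked + ([(strength, count)] if count else []),
            )

    search(0, required_mg, 0.0, [])
    assert best is not None
    return best[1], best[0]


def drug_acquisition_cost(
    regimen: Regimen,
    costs: UnitCostTable,
    bsa_m2: float = 1.8,
    include_mesna: bool = True,
) -> tuple[float, list[DrugOrder]]:
    """Per-cycle acquisition cost of a regimen's cytotoxics at whole vials.

    Mesna is co-dispensed at the ifosfamide dose for ifosfamide-containing
    regimens.  Raises :class:`ParameterError` when a required drug has no
    vial price in the country's cost table.
    """
    orders: list[DrugOrder] = []
    doses = [(c.drug, c.dose_per_m2_mg * bsa_m2) for c in regimen.components]
    if include_mesna and regimen.contains("ifosfamide"):
        ifo = next(c for c in regimen.components if c.drug == "ifosfamide")
        doses.append(("mesna", ifo.dose_per_m2_mg * bsa_m2))
    total = 0.0
    for drug, required in doses:
        if drug not in costs.vials:
            raise ParameterError(f"no vial price for {drug!r}")
        combo, cost = cheapest_vial_combination(required, costs.vials[drug])
        orders.append(
            DrugOrder(drug=drug, required_mg=required, vials=combo, cost=cost)
        )
        total += cost
    return total, orders


def supportive_medication_cost(
    regimen: Regimen,
    costs: UnitCostTable,
    resource: ResourceUseProfile,
    include_gcsf: bool = True,
) -> float:
    """Expected pre/post-chemotherapy medication cost per administration.

    The expectation sums proportion x quantity x unit cost over the
    country's medication list entries applicable to the regimen, plus
    prophylactic G-CSF at the regimen-class uptake proportion.
    """
    total = 0.0
    for item in resource.premedication:
        if ResourceUseProfile.condition_matches(item.condition, regimen):
            total += item.proportion * item.quantity * costs.get(item.cost_key)
    if include_gcsf:
        prop = resource.gcsf.proportion_for(regimen)
        total += prop * resource.gcsf.quantity * costs.get(resource.gcsf.cost_key)
    return total


def expected_toxicity_cost(tox: ToxicityProfile, costs: UnitCostTable) -> float:
    """Expected cost of managing grade 3-4 haematological events, per course.

    Events are independent, so the expectation is the probability-weighted
    sum of the four management costs.  A management cost missing from the
    country tariff (no neutropenia-management price in Sweden) counts as
    zero.
    """
    return (
        tox.p_neutropenia * costs.get("manage_neutropenia")
        + tox.p_febrile_neutropenia * costs.get("manage_febrile_neutropenia")
        + tox.p_thrombocytopenia * costs.get("manage_thrombocytopenia")
        + tox.p_anaemia * costs.get("manage_anaemia")
    )


def _bundle_cost(mapping: Mapping[str, float], costs: UnitCostTable) -> float:
    return sum(q * costs.get(key) for key, q in mapping.items())


def _per_cycle_test_cost(regimen: Regimen, params: ModelParameters) -> float:
    res = params.resource
    total = _bundle_cost(res.per_cycle_tests, params.costs)
    for condition, tests in res.per_cycle_tests_conditional:
        if ResourceUseProfile.condition_matches(condition, regimen):
            total += _bundle_cost(tests, params.costs)
    return total


def per_course_test_cost(regimen: Regimen, params: ModelParameters) -> float:
    """Once-per-course tests (e.g. cardiac assessment before anthracyclines)."""
    total = 0.0
    for condition, tests in params.resource.per_course_tests:
        if ResourceUseProfile.condition_matches(condition, regimen):
            total += _bundle_cost(tests, params.costs)
    return total


def diagnosis_cost(params: ModelParameters) -> float:
    """One-off diagnostic work-up cost per patient entering the model."""
    res = params.resource
    return _bundle_cost(res.diagnosis_visits, params.costs) + _bundle_cost(
        res.diagnosis_tests, params.costs
    )


def evaluation_event_cost(params: ModelParameters) -> float:
    """Cost of one response evaluation (imaging and laboratory bundle)."""
    return _bundle_cost(params.resource.evaluation_tests, params.costs)


def followup_monthly_cost(params: ModelParameters) -> float:
    """Expected monthly follow-up cost for responders off treatment.

    Follow-up tests and clinician visits recur at the country's follow-up
    interval; the per-visit bundle is spread uniformly per month.
    """
    res = params.resource
    bundle = _bundle_cost(res.followup_tests, params.costs) + _bundle_cost(
        res.followup_visits, params.costs
    )
    return bundle / res.followup_interval_months


def treatment_cycle_cost(
    regimen: Regimen,
    params: ModelParameters,
    category: str,
    reduced: bool = False,
) -> CostBreakdown:
    """Cost of one on-treatment cycle of ``regimen``, attributed by category.

    ``category`` names the cytotoxics bucket (first- or second-line).
    ``reduced`` applies the expected dose-reduction multiplier to the
    acquisition cost (used from the configured course cycle onward).
    """
    res = params.resource
    acq, _ = drug_acquisition_cost(regimen, params.costs, res.bsa_m2)
    if reduced:
        acq *= res.dose_reduction.multiplier
    bd = CostBreakdown()
    bd.amounts[category] = acq
    bd.amounts["hospitalisation"] = (
        regimen.admission_days * params.costs.get("hospitalisation_day")
    )
    bd.amounts["outpatient"] = (
        regimen.outpatient_attendances * params.costs.get("outpatient_attendance")
    )
    bd.amounts["cycle_tests"] = _per_cycle_test_cost(regimen, params)
    bd.amounts["premedication"] = supportive_medication_cost(
        regimen, params.costs, res
    )
    return bd


def _second_line_cycle_cost(
    params: ModelParameters, strategy: str, reduced: bool
) -> CostBreakdown:
    mix = params.mix_for(strategy)
    out = CostBreakdown()
    for name, w in mix.entries.items():
        out = out + treatment_cycle_cost(
            params.regimens[name], params, "second_line_cytotoxics", reduced
        ).scaled(w)
    return out


def cycle_cost(
    compartment_index: int,
    space: StateSpace,
    params: ModelParameters,
) -> CostBreakdown:
    """Recurring cost of one cycle spent in a compartment (unit occupancy).

    Covers treatment delivery and follow-up only; one-off event costs
    (diagnosis, response evaluations, per-course tests, toxicity
    management, palliative-care entry) are charged against the
    trajectory's event counts in :func:`aggregate_costs`.
    """
    comp = space.compartments[compartment_index]
    if comp.phase in ("dead", "palliative"):
        return CostBreakdown()
    if comp.on_treatment:
        reduced = comp.course_cycle >= params.resource.dose_reduction.from_course_cycle
        if comp.line == "first":
            return treatment_cycle_cost(
                params.regimens[space.strategy], params, "first_line_cytotoxics",
                reduced,
            )
        return _second_line_cycle_cost(params, space.strategy, reduced)
    # responder follow-up: evaluation-category costs only
    bd = CostBreakdown()
    bd.amounts["evaluations"] = followup_monthly_cost(params)
    return bd


@dataclass(frozen=True)
class CostStructure:
    """Everything needed to cost a path through the state space.

    ``per_cycle`` is a (category x compartment) matrix of recurring cost
    per unit occupancy per cycle.  Occupancy-proportional one-off costs
    (diagnosis and course-start charges, which land on single-entry
    compartments; evaluation tests, which land on the final treatment
    cycle of a line) are folded into the matrix.  The only path-dependent
    charge left outside is the one-off palliative-care cost on *entry*
    into the palliative compartment.
    """

    per_cycle: np.ndarray
    palliative_entry_cost: float

    @property
    def per_cycle_total(self) -> np.ndarray:
        return self.per_cycle.sum(axis=0)


def cost_structure(
    space: StateSpace, params: ModelParameters, strategy: str | None = None
) -> CostStructure:
    """Build the per-compartment cost matrix for a strategy's state space."""
    strategy = strategy or space.strategy
    res = params.resource

    first_pre = treatment_cycle_cost(
        params.regimens[strategy], params, "first_line_cytotoxics", reduced=False
    )
    first_post = treatment_cycle_cost(
        params.regimens[strategy], params, "first_line_cytotoxics", reduced=True
    )
    if space.include_second_line:
        second_pre = _second_line_cycle_cost(params, strategy, reduced=False)
        second_post = _second_line_cycle_cost(params, strategy, reduced=True)
    follow = CostBreakdown()
    follow.amounts["evaluations"] = followup_monthly_cost(params)

    C = np.zeros((len(CATEGORIES), space.n))
    cat_idx = {cat: k for k, cat in enumerate(CATEGORIES)}
    for j, comp in enumerate(space.compartments):
        if comp.phase in ("dead", "palliative"):
            continue
        if comp.on_treatment:
            reduced = comp.course_cycle >= res.dose_reduction.from_course_cycle
            if comp.line == "first":
                bd = first_post if reduced else first_pre
            else:
                bd = second_post if reduced else second_pre
        else:
            bd = follow
        for cat, v in bd.amounts.items():
            C[cat_idx[cat], j] = v

    # occupancy-proportional event charges
    eval_cost = evaluation_event_cost(params)
    idx = space.index
    entry1 = idx["PD1_c1"]
    C[cat_idx["diagnosis"], entry1] += diagnosis_cost(params)
    C[cat_idx["toxicity_management"], entry1] += expected_toxicity_cost(
        params.toxicity[(strategy, "first")], params.costs
    )
    C[cat_idx["cycle_tests"], entry1] += per_course_test_cost(
        params.regimens[strategy], params
    )
    eval1 = idx[f"PD1_c{params.constants.first_line_switch_cycle}"]
    C[cat_idx["evaluations"], eval1] += eval_cost
    if space.include_second_line:
        agg2 = space.second_line or second_line_aggregate(params, strategy)
        mix = params.mix_for(strategy)
        entry2 = idx["PD2_c1"]
        C[cat_idx["toxicity_management"], entry2] += expected_toxicity_cost(
            agg2.toxicity, params.costs
        )
        C[cat_idx["cycle_tests"], entry2] += sum(
            w * per_course_test_cost(params.regimens[n], params)
            for n, w in mix.entries.items()
        )
        eval2 = idx[f"PD2_c{params.constants.second_line_eval_cycles}"]
        C[cat_idx["evaluations"], eval2] += eval_cost

    return CostStructure(
        per_cycle=C,
        palliative_entry_cost=params.costs.get("palliative_care"),
    )


def aggregate_costs(
    traj: CohortTrajectory,
    params: ModelParameters,
    strategy: str | None = None,
    structure: CostStructure | None = None,
) -> CostBreakdown:
    """Discounted two-year cost breakdown for a cohort trajectory.

    Per-cycle recurring and occupancy-proportional event costs are
    occupancy-weighted; the one-off palliative-care charge is weighted by
    the palliative-entry fractions.  Second-year flows are discounted by
    1/(1+r); the grand total is the exact category sum.
    """
    if structure is None:
        structure = cost_structure(traj.space, params, strategy)
    disc = discount_factors(params.constants)
    weighted_occ = (traj.occupancy * disc[:, None]).sum(axis=0)
    amounts = structure.per_cycle @ weighted_occ
    out = {cat: float(amounts[k]) for k, cat in enumerate(CATEGORIES)}
    out["palliative_care"] += structure.palliative_entry_cost * float(
        traj.palliative_entries @ disc
    )
    bd = CostBreakdown(out)
    bd.validate()
    return bd
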