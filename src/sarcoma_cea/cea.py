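"""Incremental cost-effectiveness analysis and results rendering.

The reference strategy is the doxorubicin/ifosfamide combination and the
comparator is trabectedin monotherapy; incremental quantities are
reference minus comparator, so a negative incremental cost with positive
incremental QALYs (a negative ICER) means the reference dominates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .costing import CATEGORIES, CATEGORY_LABELS, CostBreakdown, aggregate_costs
from .engine import compute_qalys, run_cohort
from .parameters import ModelParameters

__all__ = [
    "REFERENCE_STRATEGY",
    "COMPARATOR_STRATEGY",
    "StrategyResult",
    "CEAResult",
    "evaluate_strategy",
    "incremental_analysis",
    "compare_strategies",
    "render_results",
]

REFERENCE_STRATEGY = "doxorubicin_ifosfamide"
COMPARATOR_STRATEGY = "trabectedin"


@dataclass
class StrategyResult:
    """Discounted two-year outcome of one first-line strategy."""

    strategy: str
    cost: float
    qalys: float
    breakdown: CostBreakdown = field(default_factory=CostBreakdown)
    end_state_probabilities: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of reference versus comparator.

    ``delta_cost`` and ``delta_qalys`` are reference minus comparator;
    ``icer`` is their ratio (EUR per QALY), undefined (``None``) when the
    QALY difference is zero.  ``quadrant`` classifies the reference
    strategy: ``dominant`` (cheaper, more effective), ``dominated``
    (costlier, less effective), ``trade-off NE`` (costlier, more
    effective) or ``trade-off SW`` (cheaper, less effective).
    """

    reference: str
    comparator: str
    delta_cost: float
    delta_qalys: float
    icer: float | None
    quadrant: str

    @property
    def icer_rounded(self) -> int | None:
        """ICER to the nearest euro (reporting precision)."""
        return None if self.icer is None else round(self.icer)


def _classify(delta_cost: float, delta_qalys: float) -> str:
    if delta_qalys > 0:
        return "dominant" if delta_cost < 0 else "trade-off NE"
    if delta_qalys < 0:
        return "dominated" if delta_cost > 0 else "trade-off SW"
    return "equal effectiveness"


def incremental_analysis(ref: StrategyResult, comp: StrategyResult) -> CEAResult:
    """Incremental cost, QALYs, ICER and dominance class (ref minus comp)."""
    delta_cost = ref.cost - comp.cost
    delta_qalys = ref.qalys - comp.qalys
    icer = None if delta_qalys == 0 else delta_cost / delta_qalys
    return CEAResult(
        reference=ref.strategy,
        comparator=comp.strategy,
        delta_cost=delta_cost,
        delta_qalys=delta_qalys,
        icer=icer,
        quadrant=_classify(delta_cost, delta_qalys),
    )


def evaluate_strategy(
    params: ModelParameters,
    strategy: str,
    include_second_line: bool = True,
) -> StrategyResult:
    """Run the cohort model for one strategy and total its outcomes."""
    traj = run_cohort(params, strategy, include_second_line)
    breakdown = aggregate_costs(traj, params, strategy)
    return StrategyResult(
        strategy=strategy,
        cost=breakdown.total,
        qalys=compute_qalys(traj, params.utilities, params.constants),
        breakdown=breakdown,
        end_state_probabilities=traj.end_state_probabilities(),
    )


def compare_strategies(
    params: ModelParameters,
    reference: str = REFERENCE_STRATEGY,
    comparator: str = COMPARATOR_STRATEGY,
    include_second_line: bool = True,
) -> tuple[StrategyResult, StrategyResult, CEAResult]:
    """Base-case comparison of the two first-line strategies."""
    ref = evaluate_strategy(params, reference, include_second_line)
    comp = evaluate_strategy(params, comparator, include_second_line)
    return ref, comp, incremental_analysis(ref, comp)


def render_results(
    results: list[StrategyResult],
    cea: CEAResult,
    country: str,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write deterministic CSV/JSON result tables.

    ``costs_<country>.csv`` mirrors the ten-category cost layout (amount to
    one decimal, percent of total); ``cea_<country>.json`` carries costs,
    QALYs (three decimals), the incremental comparison and end-state
    probabilities.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"costs_{country}.csv"
    with csv_path.open("w") as fh:
        fh.write("category," + ",".join(
            f"{r.strategy}_eur,{r.strategy}_pct" for r in results
        ) + "\n")
        for cat in CATEGORIES:
            cells = []
            for r in results:
                amount = r.breakdown.amounts[cat]
                pct = 100.0 * amount / r.breakdown.total if r.breakdown.total else 0.0
                cells.append(f"{amount:.1f},{pct:.1f}")
            fh.write(f"{CATEGORY_LABELS[cat]}," + ",".join(cells) + "\n")
        fh.write(
            "Total," + ",".join(f"{r.breakdown.total:.1f},100.0" for r in results) + "\n"
        )

    json_path = out_dir / f"cea_{country}.json"
    payload = {
        "country": country,
        "strategies": [
            {
                "strategy": r.strategy,
                "cost_eur": round(r.cost, 1),
                "qalys": round(r.qalys, 3),
                "end_state_probabilities": {
                    k: round(v, 4) for k, v in r.end_state_probabilities.items()
                },
                "cost_breakdown": {
                    CATEGORY_LABELS[c]: round(v, 1)
                    for c, v in r.breakdown.amounts.items()
                },
            }
            for r in results
        ],
        "incremental": {
            "reference": cea.reference,
            "comparator": cea.comparator,
            "delta_cost_eur": round(cea.delta_cost, 1),
            "delta_qalys": round(cea.delta_qalys, 3),
            "icer_eur_per_qaly": cea.icer_rounded,
            "quadrant": cea.quadrant,
        },
    }
    with json_path.open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"costs_csv": csv_path, "cea_json": json_path}
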