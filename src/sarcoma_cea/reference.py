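"""Published base-case results for the three country analyses.

The original analyses report the two-year cost breakdown and QALY totals
per country and strategy.  Those printed results are shipped here as a
fixture so that worked-example checks — incremental costs from the
printed totals, QALY gains, the Italian ICER, and category-sum
consistency — can be recomputed through the package's incremental
analysis machinery without rerunning the model.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from .cea import StrategyResult
from .costing import CATEGORIES, CostBreakdown

__all__ = ["load_published_results"]


def _reference_dir() -> Path:
    return Path(resources.files("sarcoma_cea").joinpath("data", "reference"))


def load_published_results() -> dict[tuple[str, str], StrategyResult]:
    """Published per-strategy results keyed by (country, strategy).

    Each :class:`~sarcoma_cea.cea.StrategyResult` carries the printed
    two-year total cost, the printed QALYs and the printed per-category
    cost breakdown.  Note the printed totals are reproduced as printed;
    for one column the category amounts sum to within rounding (0.2 EUR)
    of the printed total, so ``result.cost`` holds the printed total
    while ``result.breakdown.total`` is the exact category sum.
    """
    ref = _reference_dir()
    amounts: dict[tuple[str, str], dict[str, float]] = {}
    totals: dict[tuple[str, str], float] = {}
    with (ref / "published_costs.csv").open(newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["country"], row["strategy"])
            if row["category"] == "total":
                totals[key] = float(row["amount_eur"])
            else:
                amounts.setdefault(key, {})[row["category"]] = float(
                    row["amount_eur"]
                )
    qalys: dict[tuple[str, str], float] = {}
    with (ref / "published_qalys.csv").open(newline="") as fh:
        for row in csv.DictReader(fh):
            qalys[(row["country"], row["strategy"])] = float(row["qalys"])

    out: dict[tuple[str, str], StrategyResult] = {}
    for key, cats in amounts.items():
        missing = set(CATEGORIES) - set(cats)
        if missing:
            raise ValueError(f"published results for {key} missing {missing}")
        out[key] = StrategyResult(
            strategy=key[1],
            cost=totals[key],
            qalys=qalys[key],
            breakdown=CostBreakdown(dict(cats)),
        )
    return out
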