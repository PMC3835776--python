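"""Parameter packs for the sarcoma cost-utility model.

A *parameter pack* is a directory of plain-text fixtures holding one
country's complete model inputs: the chemotherapy regimen catalogue,
response (efficacy) profiles, grade 3-4 haematological toxicity profiles,
second-line treatment mixes, unit costs, health-state utilities, resource
use, cancer-mortality hazards and a background life table.  Everything the
model computes is derived from one :class:`ModelParameters` instance, so
loading is strict: referential integrity and probability coherence are
checked up front and violations raise :class:`ParameterError` with file
context.

File layout of a pack (CSV tables plus one YAML scalars file)::

    regimens.csv       regimen catalogue: components, doses, delivery
    efficacy.csv       response probabilities and median response durations
    toxicity.csv       grade 3-4 haematological event probabilities
    mixes.csv          second-line regimen mix per first-line strategy
    costs.csv          unit costs (EUR, 2010/2011 prices); drug vial strengths
    resource_use.yaml  resource-use quantities and proportions
    constants.yaml     cycle structure, horizon, discounting, utilities
    hazards.csv        monthly cancer-mortality hazards per (regimen, line)
    life_table.csv     age-indexed annual all-cause mortality

Packs for Italy, Spain and Sweden ship with the package
(:func:`load_country`); country-invariant tables live once under
``data/packs/_common`` and are merged at load time.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "HEALTH_STATES",
    "COUNTRIES",
    "ParameterError",
    "DrugComponent",
    "Regimen",
    "EfficacyProfile",
    "ToxicityProfile",
    "SecondLineMix",
    "UnitCostTable",
    "UtilitySet",
    "PremedItem",
    "GcsfRule",
    "DoseReductionRule",
    "ResourceUseProfile",
    "ModelConstants",
    "ModelParameters",
    "normalize_mix",
    "impute_missing_profiles",
    "impute_missing_hazards",
    "load_parameter_pack",
    "load_country",
    "write_parameter_pack",
]

#: Model health states.  DEAD is absorbing; CR/PR/SD are response states
#: occupied for the median response duration; PD is the entry state.
HEALTH_STATES = ("CR", "PR", "SD", "PD", "DEAD")

COUNTRIES = ("italy", "spain", "sweden")

#: Raw probability rows may drift from 1.0 by print rounding; rows within
#: this slack are renormalised proportionally, beyond it loading fails.
_ROW_SUM_SLACK = 0.02


class ParameterError(ValueError):
    """A parameter pack failed validation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugComponent:
    """One cytotoxic component of a regimen: drug name and dose per cycle."""

    drug: str
    dose_per_m2_mg: float

    def __post_init__(self) -> None:
        if self.dose_per_m2_mg < 0:
            raise ParameterError(f"negative dose for {self.drug}")


@dataclass(frozen=True)
class Regimen:
    """A chemotherapy regimen: components, delivery mode and line use.

    ``admission_days`` and ``outpatient_attendances`` are per-cycle
    expectations (an "N-M day admission" is stored at its midpoint; a
    regimen given either as an admission or as attendances carries both
    at 50/50 weight).  Oral regimens have zero of both.
    """

    name: str
    components: tuple[DrugComponent, ...]
    admission_days: float = 0.0
    outpatient_attendances: float = 0.0
    oral: bool = False
    line: str = "second"  # first / second / both

    def __post_init__(self) -> None:
        if self.admission_days < 0 or self.outpatient_attendances < 0:
            raise ParameterError(f"{self.name}: negative delivery count")
        if self.oral and (self.admission_days or self.outpatient_attendances):
            raise ParameterError(f"{self.name}: oral regimen with attendances")
        if self.line not in ("first", "second", "both"):
            raise ParameterError(f"{self.name}: bad line {self.line!r}")

    def contains(self, drug: str) -> bool:
        return any(c.drug == drug for c in self.components)

    def contains_any(self, drugs: Iterable[str]) -> bool:
        return any(self.contains(d) for d in drugs)


@dataclass(frozen=True)
class EfficacyProfile:
    """Response probabilities and median response durations for a regimen.

    Probabilities are the chance of best response CR/PR/SD/PD evaluated at
    the end of a treatment course; durations are median months spent in
    each response state before relapse to PD.  Profiles whose values were
    interpolated from donor regimens carry the ``imputed_*`` flags.
    """

    p_cr: float
    p_pr: float
    p_sd: float
    p_pd: float
    dur_cr: float = 0.0
    dur_pr: float = 0.0
    dur_sd: float = 0.0
    imputed_probs: bool = False
    imputed_durs: bool = False

    @property
    def probs(self) -> tuple[float, float, float, float]:
        return (self.p_cr, self.p_pr, self.p_sd, self.p_pd)

    @property
    def durations(self) -> tuple[float, float, float]:
        return (self.dur_cr, self.dur_pr, self.dur_sd)

    def normalized(self) -> "EfficacyProfile":
        """Proportionally renormalise the four probabilities to sum to 1.

        Printed rows are rounded to two decimals and can drift slightly;
        drift beyond ``0.02`` is treated as a data error.
        """
        s = sum(self.probs)
        if abs(s - 1.0) > _ROW_SUM_SLACK:
            raise ParameterError(
                f"response probabilities sum to {s:.4f}, not 1 "
                f"(CR={self.p_cr}, PR={self.p_pr}, SD={self.p_sd}, PD={self.p_pd})"
            )
        if s == 0:
            raise ParameterError("all response probabilities are zero")
        if abs(s - 1.0) <= 1e-12:  # already normalised; keep values bit-exact
            return self
        return replace(
            self,
            p_cr=self.p_cr / s,
            p_pr=self.p_pr / s,
            p_sd=self.p_sd / s,
            p_pd=self.p_pd / s,
        )

    def validate(self) -> None:
        for p in self.probs:
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"probability {p} outside [0, 1]")
        if abs(sum(self.probs) - 1.0) > 1e-6:
            raise ParameterError(f"probabilities sum to {sum(self.probs)}")
        for d in self.durations:
            if d < 0:
                raise ParameterError(f"negative duration {d}")


@dataclass(frozen=True)
class ToxicityProfile:
    """Per-course probabilities of grade 3-4 haematological events.

    The four events are independent categories, not mutually exclusive, so
    they need not sum to one.
    """

    p_neutropenia: float
    p_febrile_neutropenia: float
    p_thrombocytopenia: float
    p_anaemia: float
    imputed: bool = False

    @property
    def probs(self) -> tuple[float, float, float, float]:
        return (
            self.p_neutropenia,
            self.p_febrile_neutropenia,
            self.p_thrombocytopenia,
            self.p_anaemia,
        )

    def validate(self) -> None:
        for p in self.probs:
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"toxicity probability {p} outside [0, 1]")


@dataclass(frozen=True)
class SecondLineMix:
    """Distribution of second-line regimens after a given first line."""

    country: str
    first_line: str
    entries: Mapping[str, float]

    def validate(self, catalogue: Mapping[str, Regimen] | None = None) -> None:
        total = sum(self.entries.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(
                f"mix after {self.first_line} sums to {total!r}, not 1"
            )
        for name, w in self.entries.items():
            if w < 0:
                raise ParameterError(f"negative mix weight for {name}")
            if catalogue is not None and name not in catalogue:
                raise ParameterError(
                    f"mix after {self.first_line} references unknown regimen {name!r}"
                )


def normalize_mix(
    raw: Mapping[str, float | str], first_line: str, country: str
) -> SecondLineMix:
    """Build a :class:`SecondLineMix` from raw (possibly ``"<0.01"``) entries.

    Sub-rounding entries recorded as ``"<0.01"`` denote negligible use and
    are dropped; the remaining weights are rescaled to sum to one.  Raises
    :class:`ParameterError` when every entry is negligible.
    """
    numeric: dict[str, float] = {}
    for name, value in raw.items():
        if isinstance(value, str):
            if value.strip() == "<0.01":
                continue
            value = float(value)
        if value < 0:
            raise ParameterError(f"negative mix entry for {name}")
        if value > 0:
            numeric[name] = float(value)
    total = sum(numeric.values())
    if total <= 0:
        raise ParameterError(
            f"mix after {first_line} ({country}) has no entry >= 0.01"
        )
    entries = {name: w / total for name, w in numeric.items()}
    mix = SecondLineMix(country=country, first_line=first_line, entries=entries)
    mix.validate()
    return mix


@dataclass(frozen=True)
class UnitCostTable:
    """Country unit costs, EUR at 2010/2011 prices.

    ``entries`` maps resource keys to unit cost; ``units`` carries the unit
    description (per vial/day/visit/episode/patient).  ``vials`` maps drug
    names to the available vial strengths (mg) with per-vial prices.  A
    resource absent from the country's tariff list (e.g. no neutropenia
    management price in Sweden) costs zero, mirroring the source tariffs.
    """

    entries: Mapping[str, float]
    units: Mapping[str, str] = field(default_factory=dict)
    vials: Mapping[str, tuple[tuple[float, float], ...]] = field(default_factory=dict)

    def get(self, key: str) -> float:
        return float(self.entries.get(key, 0.0))

    def validate(self) -> None:
        for key, cost in self.entries.items():
            if cost < 0:
                raise ParameterError(f"negative unit cost for {key}")
        for drug, strengths in self.vials.items():
            for strength, cost in strengths:
                if strength <= 0 or cost < 0:
                    raise ParameterError(f"bad vial entry for {drug}")


@dataclass(frozen=True)
class UtilitySet:
    """Per-year health-state utility weights (time trade-off valuation)."""

    u_cr: float = 0.60
    u_pr: float = 0.51
    u_sd: float = 0.43
    u_pd: float = 0.30
    u_dead: float = 0.0

    def validate(self) -> None:
        vals = (self.u_cr, self.u_pr, self.u_sd, self.u_pd, self.u_dead)
        for u in vals:
            if not (0.0 <= u <= 1.0):
                raise ParameterError(f"utility {u} outside [0, 1]")
        if not (self.u_cr >= self.u_pr >= self.u_sd >= self.u_pd):
            raise ParameterError("utilities must be ordered CR >= PR >= SD >= PD")

    def by_state(self) -> dict[str, float]:
        return {
            "CR": self.u_cr,
            "PR": self.u_pr,
            "SD": self.u_sd,
            "PD": self.u_pd,
            "DEAD": self.u_dead,
        }


@dataclass(frozen=True)
class PremedItem:
    """One pre/post-chemotherapy medication given per administration."""

    cost_key: str
    quantity: float
    proportion: float
    condition: str = "all"  # see ResourceUseProfile.condition_matches


@dataclass(frozen=True)
class GcsfRule:
    """Prophylactic G-CSF: product and per-regimen uptake proportions."""

    cost_key: str
    quantity: float
    uptake: tuple[tuple[str, float], ...]  # (condition, proportion), first match

    def proportion_for(self, regimen: Regimen) -> float:
        for condition, prop in self.uptake:
            if ResourceUseProfile.condition_matches(condition, regimen):
                return prop
        return 0.0


@dataclass(frozen=True)
class DoseReductionRule:
    """Expected dose reduction applied late in a course.

    ``uptake`` is the proportion of patients requiring a reduction,
    ``magnitude`` the fractional dose cut; acquisition costs from
    ``from_course_cycle`` onward are multiplied by
    ``1 - uptake * magnitude``.
    """

    uptake: float = 0.18
    magnitude: float = 0.23
    from_course_cycle: int = 4

    @property
    def multiplier(self) -> float:
        return 1.0 - self.uptake * self.magnitude


@dataclass(frozen=True)
class ResourceUseProfile:
    """Country resource-use quantities outside drug acquisition.

    Quantities derived from interview ranges are stored as mid-range point
    estimates; every field can be overridden in ``resource_use.yaml``.
    Test/visit mappings are ``resource key -> expected count or proportion``.
    """

    bsa_m2: float
    diagnosis_visits: Mapping[str, float]
    diagnosis_tests: Mapping[str, float]
    evaluation_tests: Mapping[str, float]
    per_cycle_tests: Mapping[str, float]
    per_cycle_tests_conditional: tuple[tuple[str, Mapping[str, float]], ...]
    per_course_tests: tuple[tuple[str, Mapping[str, float]], ...]
    followup_interval_months: float
    followup_tests: Mapping[str, float]
    followup_visits: Mapping[str, float]
    premedication: tuple[PremedItem, ...]
    gcsf: GcsfRule
    dose_reduction: DoseReductionRule
    palliative_one_off: bool = True

    @staticmethod
    def condition_matches(condition: str, regimen: Regimen) -> bool:
        """Evaluate a regimen-applicability condition.

        Grammar: ``all`` | ``regimen:<name>`` | ``contains:<drug>`` |
        ``not_contains:<drug>`` | ``contains_any:<drug>,<drug>,...``.
        """
        if condition == "all":
            return True
        kind, _, arg = condition.partition(":")
        if kind == "regimen":
            return regimen.name == arg
        if kind == "contains":
            return regimen.contains(arg)
        if kind == "not_contains":
            return not regimen.contains(arg)
        if kind == "contains_any":
            return regimen.contains_any(a.strip() for a in arg.split(","))
        raise ParameterError(f"unknown condition {condition!r}")

    def validate(self) -> None:
        if self.bsa_m2 <= 0:
            raise ParameterError("BSA must be positive")
        for mapping in (
            self.diagnosis_tests,
            self.evaluation_tests,
            self.followup_tests,
        ):
            for key, p in mapping.items():
                if p < 0:
                    raise ParameterError(f"negative proportion for {key}")
        for item in self.premedication:
            if not (0.0 <= item.proportion <= 1.0):
                raise ParameterError(
                    f"premedication proportion {item.proportion} outside [0, 1]"
                )
            if item.quantity < 0:
                raise ParameterError("negative premedication quantity")
        if not (0.0 <= self.dose_reduction.uptake <= 1.0):
            raise ParameterError("dose-reduction uptake outside [0, 1]")
        if not (0.0 <= self.dose_reduction.magnitude <= 1.0):
            raise ParameterError("dose-reduction magnitude outside [0, 1]")


@dataclass(frozen=True)
class ModelConstants:
    """Model structure constants shared by every analysis."""

    cycle_length_months: float = 1.0
    horizon_cycles: int = 24
    discount_rate: float = 0.03
    first_line_switch_cycle: int = 3
    second_line_eval_cycles: int = 3
    mean_course_cycles: int = 6
    psa_iterations: int = 10_000
    dsa_fraction: float = 0.20
    ceac_reference_threshold: float = 35_000.0

    def validate(self) -> None:
        for name in (
            "cycle_length_months",
            "horizon_cycles",
            "discount_rate",
            "first_line_switch_cycle",
            "second_line_eval_cycles",
            "mean_course_cycles",
            "psa_iterations",
            "dsa_fraction",
            "ceac_reference_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"constant {name} must be positive")
        if self.horizon_cycles != 24:
            raise ParameterError("model horizon is fixed at 24 monthly cycles")


@dataclass
class ModelParameters:
    """One country's complete, validated model input set."""

    country: str
    regimens: dict[str, Regimen]
    efficacy: dict[tuple[str, str], EfficacyProfile]
    toxicity: dict[tuple[str, str], ToxicityProfile]
    mixes: dict[str, SecondLineMix]
    costs: UnitCostTable
    utilities: UtilitySet
    resource: ResourceUseProfile
    constants: ModelConstants
    hazards: dict[tuple[str, str], float]
    life_table: "LifeTable"

    def mix_for(self, first_line: str) -> SecondLineMix:
        try:
            return self.mixes[first_line]
        except KeyError:
            raise ParameterError(
                f"no second-line mix after first-line {first_line!r}"
            ) from None

    def active_second_line(self, first_line: str) -> list[str]:
        return sorted(self.mix_for(first_line).entries)

    def validate(self) -> None:
        self.costs.validate()
        self.utilities.validate()
        self.resource.validate()
        self.constants.validate()
        self.life_table.validate()
        for key, prof in self.efficacy.items():
            try:
                prof.validate()
            except ParameterError as exc:
                raise ParameterError(f"efficacy {key}: {exc}") from None
        for key, prof in self.toxicity.items():
            try:
                prof.validate()
            except ParameterError as exc:
                raise ParameterError(f"toxicity {key}: {exc}") from None
        for mix in self.mixes.values():
            mix.validate(self.regimens)
        for (name, line), rate in self.hazards.items():
            if rate < 0:
                raise ParameterError(f"negative hazard for {(name, line)}")
        # referential integrity for every regimen the strategies can reach
        for first_line, mix in self.mixes.items():
            if first_line not in self.regimens:
                raise ParameterError(f"unknown first-line regimen {first_line!r}")
            self._check_complete(first_line, "first")
            for name in mix.entries:
                self._check_complete(name, "second")

    def _check_complete(self, name: str, line: str) -> None:
        if name not in self.regimens:
            raise ParameterError(f"regimen {name!r} missing from catalogue")
        if (name, line) not in self.efficacy:
            raise ParameterError(f"no {line}-line efficacy profile for {name!r}")
        if (name, line) not in self.toxicity:
            raise ParameterError(f"no {line}-line toxicity profile for {name!r}")
        if (name, line) not in self.hazards:
            raise ParameterError(f"no {line}-line cancer hazard for {name!r}")
        for comp in self.regimens[name].components:
            if comp.drug not in self.costs.vials:
                raise ParameterError(
                    f"{self.country}: no vial price for {comp.drug!r} "
                    f"(required by {name!r})"
                )


# ---------------------------------------------------------------------------
# imputation of missing second-line profiles
# ---------------------------------------------------------------------------

# Regimens whose second-line response probabilities were never published:
# donor set and rule per the clinical rationale (like-for-like class match
# or average over the published second-line combination regimens).
_EFFICACY_PROB_DONORS: dict[str, tuple[str, ...]] = {
    "ifosfamide_epirubicin": ("doxorubicin_ifosfamide",),
    "liposomal_doxorubicin": ("doxorubicin",),
    "cyvadic": ("doxorubicin_ifosfamide", "gemcitabine_docetaxel", "gemcitabine_dacarbazine"),
    "trofosfamide_etoposide": ("doxorubicin_ifosfamide", "gemcitabine_docetaxel", "gemcitabine_dacarbazine"),
    "gemcitabine_paclitaxel": ("doxorubicin_ifosfamide", "gemcitabine_docetaxel", "gemcitabine_dacarbazine"),
}

#: Second-line regimens with published median response durations; every
#: other second-line regimen takes the average of these (trabectedin is
#: deliberately excluded from the donor pool as the only new-generation
#: agent, and zero donor durations are treated as not observed).
_DURATION_DONORS = ("ifosfamide", "gemcitabine_dacarbazine", "gemcitabine")

#: Published second-line *combination* regimens: donor pool for missing
#: combination-regimen toxicity profiles.
_TOXICITY_COMBO_DONORS = (
    "gemcitabine_dacarbazine",
    "gemcitabine_docetaxel",
    "gemcitabine_vinorelbine",
)
_TOXICITY_MISSING = (
    "doxorubicin_ifosfamide",
    "ifosfamide_epirubicin",
    "cyvadic",
    "gemcitabine_paclitaxel",
    "trofosfamide_etoposide",
)


def _mean(values: Iterable[float]) -> float:
    vals = list(values)
    if not vals:
        raise ParameterError("no donor values available for imputation")
    return sum(vals) / len(vals)


def _round2(x: float) -> float:
    """Round to two decimals with halves up (the printed convention)."""
    return math.floor(x * 100.0 + 0.5) / 100.0


def _mean_duration(donors: list[EfficacyProfile], attr: str) -> float:
    # a zero median duration means "no such responses observed", not an
    # observed zero-month duration; exclude it from the donor average
    vals = [getattr(d, attr) for d in donors if getattr(d, attr) > 0]
    return _mean(vals) if vals else 0.0


def impute_missing_profiles(
    regimens: Mapping[str, Regimen],
    efficacy: Mapping[tuple[str, str], EfficacyProfile],
    toxicity: Mapping[tuple[str, str], ToxicityProfile],
) -> tuple[dict[tuple[str, str], EfficacyProfile], dict[tuple[str, str], ToxicityProfile]]:
    """Fill second-line profiles that were never published from donor rows.

    Response probabilities use like-for-like donors (ifosfamide/epirubicin
    from doxorubicin/ifosfamide; liposomal doxorubicin from doxorubicin) or
    the average over the published second-line combination regimens.
    Response durations use the average of the three second-line regimens
    with published durations.  Toxicity for unpublished combination
    regimens uses the average over the published combination regimens.
    Entries already present are left untouched; imputed entries are
    flagged.  The operation is deterministic and independent of mapping
    iteration order.
    """
    eff = dict(efficacy)
    tox = dict(toxicity)

    for name in sorted(regimens):
        key = (name, "second")
        if regimens[name].line == "first":
            continue
        if key not in eff:
            donors_names = _EFFICACY_PROB_DONORS.get(
                name,
                ("doxorubicin_ifosfamide", "gemcitabine_docetaxel", "gemcitabine_dacarbazine"),
            )
            donors = [eff[(d, "second")] for d in donors_names if (d, "second") in eff]
            if not donors:
                raise ParameterError(f"no efficacy donors for {name!r}")
            if len(donors) == 1:
                # like-for-like rule: an exact copy of the single donor
                eff[key] = replace(donors[0], imputed_probs=True)
            else:
                eff[key] = EfficacyProfile(
                    p_cr=_round2(_mean(d.p_cr for d in donors)),
                    p_pr=_round2(_mean(d.p_pr for d in donors)),
                    p_sd=_round2(_mean(d.p_sd for d in donors)),
                    p_pd=_round2(_mean(d.p_pd for d in donors)),
                    imputed_probs=True,
                ).normalized()
        prof = eff[key]
        if prof.dur_cr == prof.dur_pr == prof.dur_sd == 0.0 and prof.p_cr + prof.p_pr + prof.p_sd > 0:
            dur_donors = [
                eff[(d, "second")] for d in _DURATION_DONORS if (d, "second") in eff
            ]
            if name not in _DURATION_DONORS and dur_donors:
                eff[key] = replace(
                    prof,
                    dur_cr=_round2(_mean_duration(dur_donors, "dur_cr")),
                    dur_pr=_round2(_mean_duration(dur_donors, "dur_pr")),
                    dur_sd=_round2(_mean_duration(dur_donors, "dur_sd")),
                    imputed_durs=True,
                )

    combo_donors = [
        tox[(d, "second")] for d in _TOXICITY_COMBO_DONORS if (d, "second") in tox
    ]
    for name in sorted(regimens):
        key = (name, "second")
        if regimens[name].line == "first" or key in tox:
            continue
        if not combo_donors:
            raise ParameterError(f"no toxicity donors for {name!r}")
        tox[key] = ToxicityProfile(
            p_neutropenia=_round2(_mean(d.p_neutropenia for d in combo_donors)),
            p_febrile_neutropenia=_round2(
                _mean(d.p_febrile_neutropenia for d in combo_donors)
            ),
            p_thrombocytopenia=_round2(
                _mean(d.p_thrombocytopenia for d in combo_donors)
            ),
            p_anaemia=_round2(_mean(d.p_anaemia for d in combo_donors)),
            imputed=True,
        )
    return eff, tox


#: Mortality-hazard imputation: regimens without published second-line
#: survival take either a like-for-like donor or the average of the three
#: regimen classes with published curves.
_HAZARD_DONORS: dict[str, tuple[str, ...]] = {
    "doxorubicin": ("ifosfamide",),
    "liposomal_doxorubicin": ("ifosfamide",),
    "doxorubicin_ifosfamide": ("ifosfamide", "trabectedin"),
    "ifosfamide_epirubicin": ("ifosfamide", "trabectedin"),
}
_HAZARD_DEFAULT_DONORS = ("gemcitabine", "ifosfamide", "trabectedin")


def impute_missing_hazards(
    regimens: Mapping[str, Regimen],
    hazards: Mapping[tuple[str, str], float],
) -> dict[tuple[str, str], float]:
    """Fill second-line cancer hazards from donor regimens (averaging)."""
    out = dict(hazards)
    for name in sorted(regimens):
        key = (name, "second")
        if regimens[name].line == "first" or key in out:
            continue
        donors = _HAZARD_DONORS.get(name, _HAZARD_DEFAULT_DONORS)
        vals = [out[(d, "second")] for d in donors if (d, "second") in out]
        if not vals:
            raise ParameterError(f"no hazard donors for {name!r}")
        out[key] = _mean(vals)
    return out


# ---------------------------------------------------------------------------
# pack I/O
# ---------------------------------------------------------------------------


def _read_csv(path: Path) -> list[dict[str, str]]:
    if not path.exists():
        raise ParameterError(f"missing pack file: {path}")
    with path.open(newline="") as fh:
        return list(csv.DictReader(fh))


def _require(row: Mapping[str, str], col: str, path: Path) -> str:
    if col not in row or row[col] is None:
        raise ParameterError(f"{path.name}: missing column {col!r}")
    return row[col]


def _pack_file(path: Path, common: Path | None, name: str) -> Path:
    local = path / name
    if local.exists():
        return local
    if common is not None and (common / name).exists():
        return common / name
    return local  # triggers missing-file error downstream


def load_parameter_pack(path: str | Path, common: str | Path | None = None) -> ModelParameters:
    """Load and validate a parameter pack directory.

    ``common`` optionally names a directory with country-invariant tables;
    files present in ``path`` take precedence.  Raises
    :class:`ParameterError` naming the offending file/row on any
    validation failure.
    """
    from .survival import LifeTable  # local import to avoid a cycle

    path = Path(path)
    common = Path(common) if common is not None else None

    # regimens
    regimens: dict[str, Regimen] = {}
    reg_rows: dict[str, list[dict[str, str]]] = {}
    reg_path = _pack_file(path, common, "regimens.csv")
    for row in _read_csv(reg_path):
        reg_rows.setdefault(_require(row, "regimen", reg_path), []).append(row)
    for name, rows in reg_rows.items():
        components = tuple(
            DrugComponent(r["drug"], float(r["dose_per_m2_mg"])) for r in rows
        )
        first = rows[0]
        regimens[name] = Regimen(
            name=name,
            components=components,
            admission_days=float(first["admission_days"]),
            outpatient_attendances=float(first["outpatient_attendances"]),
            oral=first["oral"].strip().lower() in ("1", "true", "yes"),
            line=first["line"],
        )

    # efficacy
    efficacy: dict[tuple[str, str], EfficacyProfile] = {}
    eff_path = _pack_file(path, common, "efficacy.csv")
    for row in _read_csv(eff_path):
        name = _require(row, "regimen", eff_path)
        try:
            profile = EfficacyProfile(
                p_cr=float(row["p_cr"]),
                p_pr=float(row["p_pr"]),
                p_sd=float(row["p_sd"]),
                p_pd=float(row["p_pd"]),
                dur_cr=float(row["dur_cr"]),
                dur_pr=float(row["dur_pr"]),
                dur_sd=float(row["dur_sd"]),
                imputed_probs=row.get("imputed_probs", "0") == "1",
                imputed_durs=row.get("imputed_durs", "0") == "1",
            ).normalized()
        except ParameterError as exc:
            raise ParameterError(
                f"{eff_path.name}: regimen {name!r} ({row['line']}-line): {exc}"
            ) from None
        efficacy[(name, row["line"])] = profile

    # toxicity
    toxicity: dict[tuple[str, str], ToxicityProfile] = {}
    tox_path = _pack_file(path, common, "toxicity.csv")
    for row in _read_csv(tox_path):
        toxicity[(_require(row, "regimen", tox_path), row["line"])] = ToxicityProfile(
            p_neutropenia=float(row["p_neutropenia"]),
            p_febrile_neutropenia=float(row["p_febrile_neutropenia"]),
            p_thrombocytopenia=float(row["p_thrombocytopenia"]),
            p_anaemia=float(row["p_anaemia"]),
            imputed=row.get("imputed", "0") == "1",
        )

    # constants + utilities + country
    const_path = _pack_file(path, common, "constants.yaml")
    if not const_path.exists():
        raise ParameterError(f"missing pack file: {const_path}")
    with const_path.open() as fh:
        scalars = yaml.safe_load(fh)
    country = scalars["country"]
    util = scalars.get("utilities", {})
    utilities = UtilitySet(
        u_cr=float(util.get("cr", 0.60)),
        u_pr=float(util.get("pr", 0.51)),
        u_sd=float(util.get("sd", 0.43)),
        u_pd=float(util.get("pd", 0.30)),
    )
    const_kwargs = {
        k: v for k, v in scalars.items() if k not in ("country", "utilities")
    }
    constants = ModelConstants(**const_kwargs)

    # mixes
    raw_mixes: dict[str, dict[str, str]] = {}
    mix_path = _pack_file(path, common, "mixes.csv")
    for row in _read_csv(mix_path):
        raw_mixes.setdefault(_require(row, "first_line", mix_path), {})[
            row["second_line"]
        ] = row["probability"]
    mixes = {
        fl: normalize_mix(raw, fl, country) for fl, raw in raw_mixes.items()
    }

    # costs
    entries: dict[str, float] = {}
    units: dict[str, str] = {}
    vials: dict[str, list[tuple[float, float]]] = {}
    cost_path = _pack_file(path, common, "costs.csv")
    for row in _read_csv(cost_path):
        key = _require(row, "resource", cost_path)
        cost = float(row["cost_eur"])
        if cost < 0:
            raise ParameterError(f"{cost_path.name}: negative cost for {key!r}")
        strength = row.get("vial_strength_mg", "")
        if strength:
            vials.setdefault(key, []).append((float(strength), cost))
        else:
            entries[key] = cost
            units[key] = row.get("unit", "")
    costs = UnitCostTable(
        entries=entries,
        units=units,
        vials={k: tuple(sorted(v)) for k, v in vials.items()},
    )

    # resource use
    ru_path = _pack_file(path, common, "resource_use.yaml")
    if not ru_path.exists():
        raise ParameterError(f"missing pack file: {ru_path}")
    with ru_path.open() as fh:
        ru = yaml.safe_load(fh)
    resource = ResourceUseProfile(
        bsa_m2=float(ru["bsa_m2"]),
        diagnosis_visits=dict(ru["diagnosis"]["visits"]),
        diagnosis_tests=dict(ru["diagnosis"]["tests"]),
        evaluation_tests=dict(ru["evaluation_tests"]),
        per_cycle_tests=dict(ru["per_cycle_tests"]["all"]),
        per_cycle_tests_conditional=tuple(
            (item["condition"], dict(item["tests"]))
            for item in ru["per_cycle_tests"].get("conditional", [])
        ),
        per_course_tests=tuple(
            (item["condition"], dict(item["tests"]))
            for item in ru.get("per_course_tests", [])
        ),
        followup_interval_months=float(ru["followup"]["interval_months"]),
        followup_tests=dict(ru["followup"]["tests"]),
        followup_visits=dict(ru["followup"]["visits"]),
        premedication=tuple(
            PremedItem(
                cost_key=item["cost_key"],
                quantity=float(item["quantity"]),
                proportion=float(item["proportion"]),
                condition=item.get("condition", "all"),
            )
            for item in ru.get("premedication", [])
        ),
        gcsf=GcsfRule(
            cost_key=ru["gcsf"]["cost_key"],
            quantity=float(ru["gcsf"].get("quantity", 1.0)),
            uptake=tuple(
                (item["condition"], float(item["proportion"]))
                for item in ru["gcsf"]["uptake"]
            ),
        ),
        dose_reduction=DoseReductionRule(
            uptake=float(ru["dose_reduction"]["uptake"]),
            magnitude=float(ru["dose_reduction"]["magnitude"]),
            from_course_cycle=int(ru["dose_reduction"]["from_course_cycle"]),
        ),
        palliative_one_off=bool(ru.get("palliative", {}).get("one_off", True)),
    )

    # hazards
    hazards: dict[tuple[str, str], float] = {}
    hz_path = _pack_file(path, common, "hazards.csv")
    for row in _read_csv(hz_path):
        hazards[(_require(row, "regimen", hz_path), row["line"])] = float(
            row["rate_per_month"]
        )

    # life table
    lt_path = _pack_file(path, common, "life_table.csv")
    lt_rows = _read_csv(lt_path)
    life_table = LifeTable(
        ages=tuple(int(r["age"]) for r in lt_rows),
        annual_mortality=tuple(float(r["annual_mortality"]) for r in lt_rows),
    )

    efficacy, toxicity = impute_missing_profiles(regimens, efficacy, toxicity)
    hazards = impute_missing_hazards(regimens, hazards)

    params = ModelParameters(
        country=country,
        regimens=regimens,
        efficacy=efficacy,
        toxicity=toxicity,
        mixes=mixes,
        costs=costs,
        utilities=utilities,
        resource=resource,
        constants=constants,
        hazards=hazards,
        life_table=life_table,
    )
    params.validate()
    return params


def _packaged_dir(name: str) -> Path:
    return Path(resources.files("sarcoma_cea").joinpath("data", "packs", name))


def load_country(country: str) -> ModelParameters:
    """Load the packaged parameter pack for ``italy``, ``spain`` or ``sweden``."""
    country = country.lower()
    if country not in COUNTRIES:
        raise ParameterError(f"unknown country {country!r}; expected {COUNTRIES}")
    return load_parameter_pack(_packaged_dir(country), common=_packaged_dir("_common"))


def write_parameter_pack(params: ModelParameters, path: str | Path) -> None:
    """Write a self-contained pack directory that reloads to equal values.

    Note: second-line profiles and hazards that were imputed at load time
    are written out explicitly (with their imputed flags), so a written
    pack is complete without re-running the imputation rules.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    def dump(name: str, header: list[str], rows: list[list]) -> None:
        with (path / name).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(rows)

    dump(
        "regimens.csv",
        ["regimen", "drug", "dose_per_m2_mg", "admission_days",
         "outpatient_attendances", "oral", "line"],
        [
            [r.name, c.drug, repr(c.dose_per_m2_mg), repr(r.admission_days),
             repr(r.outpatient_attendances), int(r.oral), r.line]
            for r in params.regimens.values()
            for c in r.components
        ],
    )
    dump(
        "efficacy.csv",
        ["regimen", "line", "p_cr", "p_pr", "p_sd", "p_pd",
         "dur_cr", "dur_pr", "dur_sd", "imputed_probs", "imputed_durs"],
        [
            [name, line] + [repr(v) for v in (*p.probs, *p.durations)]
            + [int(p.imputed_probs), int(p.imputed_durs)]
            for (name, line), p in sorted(params.efficacy.items())
        ],
    )
    dump(
        "toxicity.csv",
        ["regimen", "line", "p_neutropenia", "p_febrile_neutropenia",
         "p_thrombocytopenia", "p_anaemia", "imputed"],
        [
            [name, line] + [repr(v) for v in p.probs] + [int(p.imputed)]
            for (name, line), p in sorted(params.toxicity.items())
        ],
    )
    dump(
        "mixes.csv",
        ["first_line", "second_line", "probability"],
        [
            [fl, sl, repr(w)]
            for fl, mix in sorted(params.mixes.items())
            for sl, w in sorted(mix.entries.items())
        ],
    )
    dump(
        "costs.csv",
        ["resource", "unit", "cost_eur", "vial_strength_mg"],
        [
            [key, params.costs.units.get(key, ""), repr(cost), ""]
            for key, cost in sorted(params.costs.entries.items())
        ]
        + [
            [drug, "per vial", repr(cost), repr(strength)]
            for drug, strengths in sorted(params.costs.vials.items())
            for strength, cost in strengths
        ],
    )
    dump(
        "hazards.csv",
        ["regimen", "line", "rate_per_month"],
        [
            [name, line, repr(rate)]
            for (name, line), rate in sorted(params.hazards.items())
        ],
    )
    dump(
        "life_table.csv",
        ["age", "annual_mortality"],
        [
            [age, repr(q)]
            for age, q in zip(params.life_table.ages, params.life_table.annual_mortality)
        ],
    )

    ru = params.resource
    with (path / "resource_use.yaml").open("w") as fh:
        yaml.safe_dump(
            {
                "bsa_m2": ru.bsa_m2,
                "diagnosis": {
                    "visits": dict(ru.diagnosis_visits),
                    "tests": dict(ru.diagnosis_tests),
                },
                "evaluation_tests": dict(ru.evaluation_tests),
                "per_cycle_tests": {
                    "all": dict(ru.per_cycle_tests),
                    "conditional": [
                        {"condition": cond, "tests": dict(tests)}
                        for cond, tests in ru.per_cycle_tests_conditional
                    ],
                },
                "per_course_tests": [
                    {"condition": cond, "tests": dict(tests)}
                    for cond, tests in ru.per_course_tests
                ],
                "followup": {
                    "interval_months": ru.followup_interval_months,
                    "tests": dict(ru.followup_tests),
                    "visits": dict(ru.followup_visits),
                },
                "premedication": [
                    {
                        "cost_key": p.cost_key,
                        "quantity": p.quantity,
                        "proportion": p.proportion,
                        "condition": p.condition,
                    }
                    for p in ru.premedication
                ],
                "gcsf": {
                    "cost_key": ru.gcsf.cost_key,
                    "quantity": ru.gcsf.quantity,
                    "uptake": [
                        {"condition": c, "proportion": p} for c, p in ru.gcsf.uptake
                    ],
                },
                "dose_reduction": {
                    "uptake": ru.dose_reduction.uptake,
                    "magnitude": ru.dose_reduction.magnitude,
                    "from_course_cycle": ru.dose_reduction.from_course_cycle,
                },
                "palliative": {"one_off": ru.palliative_one_off},
            },
            fh,
            sort_keys=False,
        )
    with (path / "constants.yaml").open("w") as fh:
        c = params.constants
        yaml.safe_dump(
            {
                "country": params.country,
                "utilities": {
                    "cr": params.utilities.u_cr,
                    "pr": params.utilities.u_pr,
                    "sd": params.utilities.u_sd,
                    "pd": params.utilities.u_pd,
                },
                "cycle_length_months": c.cycle_length_months,
                "horizon_cycles": c.horizon_cycles,
                "discount_rate": c.discount_rate,
                "first_line_switch_cycle": c.first_line_switch_cycle,
                "second_line_eval_cycles": c.second_line_eval_cycles,
                "mean_course_cycles": c.mean_course_cycles,
                "psa_iterations": c.psa_iterations,
                "dsa_fraction": c.dsa_fraction,
                "ceac_reference_threshold": c.ceac_reference_threshold,
            },
            fh,
            sort_keys=False,
        )
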