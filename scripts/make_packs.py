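"""Regenerate the packaged country parameter packs (fixture CSV/YAML files)."""

import csv
from pathlib import Path

import yaml

ROOT = Path(__file__).resolve().parents[1] / "src" / "sarcoma_cea" / "data" / "packs"

# regimen, [(drug, dose mg/m2)], admission_days, outpatient, oral, line
REGIMENS = [
    ("cyvadic", [("cyclophosphamide", 600), ("vincristine", 1), ("doxorubicin", 30), ("dacarbazine", 250)], 0, 4, 0, "second"),
    ("docetaxel", [("docetaxel", 100)], 0, 1, 0, "second"),
    ("doxorubicin", [("doxorubicin", 75)], 0, 1, 0, "second"),
    ("doxorubicin_ifosfamide", [("doxorubicin", 66), ("ifosfamide", 8500)], 3.5, 0, 0, "both"),
    ("ifosfamide", [("ifosfamide", 12500)], 2.0, 1.0, 0, "second"),  # 4-day admission or 2 attendances, 50/50
    ("ifosfamide_epirubicin", [("epirubicin", 100), ("ifosfamide", 5000)], 3, 0, 0, "second"),
    ("gemcitabine", [("gemcitabine", 1000)], 0, 2, 0, "second"),
    ("gemcitabine_dacarbazine", [("gemcitabine", 1766), ("dacarbazine", 700)], 0, 2, 0, "second"),
    ("gemcitabine_docetaxel", [("gemcitabine", 1000), ("docetaxel", 75)], 0, 2, 0, "second"),
    ("gemcitabine_paclitaxel", [("gemcitabine", 1000), ("paclitaxel", 125)], 0, 2, 0, "second"),
    ("gemcitabine_vinorelbine", [("gemcitabine", 1250), ("vinorelbine", 25)], 0, 2, 0, "second"),
    ("liposomal_doxorubicin", [("liposomal_doxorubicin", 50)], 0, 1, 0, "second"),
    ("trabectedin", [("trabectedin", 1.3)], 2, 0, 0, "both"),
    ("trofosfamide", [("trofosfamide", 200)], 0, 0, 1, "second"),
    ("trofosfamide_etoposide", [("trofosfamide", 150), ("etoposide", 25)], 0, 0, 1, "second"),
]

# regimen, line, p_cr, p_pr, p_sd, p_pd, dur_cr, dur_pr, dur_sd, imp_probs, imp_durs
EFFICACY = [
    ("doxorubicin_ifosfamide", "first", 0.06, 0.21, 0.38, 0.35, 15.44, 7.69, 6.41, 0, 0),
    ("trabectedin", "first", 0.03, 0.11, 0.14, 0.72, 17.74, 8.75, 7.48, 0, 0),
    ("cyvadic", "second", 0.03, 0.19, 0.39, 0.39, 12.13, 6.57, 5.75, 1, 1),
    ("docetaxel", "second", 0.00, 0.11, 0.25, 0.64, 0.00, 6.60, 7.17, 0, 0),
    ("doxorubicin", "second", 0.02, 0.07, 0.31, 0.61, 12.13, 6.57, 5.75, 0, 1),
    ("doxorubicin_ifosfamide", "second", 0.05, 0.27, 0.37, 0.31, 12.13, 6.57, 5.75, 0, 1),
    ("gemcitabine", "second", 0.00, 0.08, 0.33, 0.59, 0.00, 4.46, 3.86, 0, 0),
    ("gemcitabine_dacarbazine", "second", 0.01, 0.10, 0.39, 0.51, 10.48, 6.50, 5.79, 0, 0),
    ("gemcitabine_docetaxel", "second", 0.05, 0.19, 0.41, 0.35, 12.13, 6.57, 5.75, 0, 1),
    ("gemcitabine_paclitaxel", "second", 0.03, 0.19, 0.39, 0.39, 12.13, 6.57, 5.75, 1, 1),
    ("gemcitabine_vinorelbine", "second", 0.02, 0.10, 0.10, 0.78, 16.10, 16.10, 9.60, 0, 0),
    ("ifosfamide", "second", 0.02, 0.13, 0.24, 0.61, 13.77, 8.75, 7.61, 0, 0),
    ("ifosfamide_epirubicin", "second", 0.05, 0.27, 0.37, 0.31, 12.13, 6.57, 5.75, 1, 1),
    ("liposomal_doxorubicin", "second", 0.02, 0.07, 0.31, 0.61, 12.13, 6.57, 5.75, 1, 1),
    ("trabectedin", "second", 0.005, 0.07, 0.44, 0.49, 16.14, 10.25, 8.91, 0, 0),  # CR "<0.01" stored as 0.005
    ("trofosfamide", "second", 0.00, 0.03, 0.19, 0.79, 12.13, 6.57, 5.75, 0, 1),
    ("trofosfamide_etoposide", "second", 0.03, 0.19, 0.39, 0.39, 12.13, 6.57, 5.75, 1, 1),
]

# regimen, line, neutropenia, febrile neutropenia, thrombocytopenia, anaemia, imputed
TOXICITY = [
    ("doxorubicin_ifosfamide", "first", 0.82, 0.12, 0.23, 0.35, 0),
    ("trabectedin", "first", 0.33, 0.00, 0.00, 0.03, 0),
    ("cyvadic", "second", 0.52, 0.19, 0.17, 0.16, 1),
    ("docetaxel", "second", 0.90, 0.12, 0.03, 0.08, 0),
    ("doxorubicin", "second", 0.84, 0.19, 0.09, 0.18, 0),
    ("doxorubicin_ifosfamide", "second", 0.52, 0.19, 0.17, 0.18, 1),
    ("gemcitabine", "second", 0.18, 0.07, 0.18, 0.11, 0),
    ("gemcitabine_dacarbazine", "second", 0.46, 0.19, 0.12, 0.23, 0),
    ("gemcitabine_docetaxel", "second", 0.31, 0.09, 0.33, 0.18, 0),
    ("gemcitabine_paclitaxel", "second", 0.52, 0.19, 0.17, 0.16, 1),
    ("gemcitabine_vinorelbine", "second", 0.38, 0.08, 0.10, 0.05, 0),
    ("ifosfamide", "second", 0.82, 0.39, 0.13, 0.12, 0),
    ("ifosfamide_epirubicin", "second", 0.52, 0.19, 0.17, 0.18, 1),
    ("liposomal_doxorubicin", "second", 0.07, 0.02, 0.00, 0.35, 1),
    ("trabectedin", "second", 0.50, 0.06, 0.16, 0.18, 0),
    ("trofosfamide", "second", 0.52, 0.19, 0.17, 0.25, 1),
    ("trofosfamide_etoposide", "second", 0.52, 0.19, 0.17, 0.16, 1),
]

# country -> first_line -> {second_line: prob or "<0.01"}
MIXES = {
    "italy": {
        "doxorubicin_ifosfamide": {
            "cyvadic": "<0.01", "gemcitabine_dacarbazine": "<0.01",
            "gemcitabine_docetaxel": 0.18, "gemcitabine_paclitaxel": "<0.01",
            "gemcitabine_vinorelbine": "<0.01", "gemcitabine": "<0.01",
            "ifosfamide": 0.20, "liposomal_doxorubicin": 0.12,
            "trofosfamide": "<0.01", "trabectedin": 0.50,
        },
        "trabectedin": {
            "docetaxel": 0.26, "doxorubicin_ifosfamide": "<0.01",
            "doxorubicin": "<0.01", "gemcitabine_docetaxel": 0.05,
            "ifosfamide_epirubicin": 0.16, "ifosfamide": 0.53,
            "trofosfamide_etoposide": "<0.01",
        },
    },
    "spain": {
        "doxorubicin_ifosfamide": {
            "cyvadic": "<0.01", "gemcitabine_dacarbazine": 0.12,
            "gemcitabine_docetaxel": 0.20, "gemcitabine_paclitaxel": 0.10,
            "gemcitabine_vinorelbine": 0.08, "gemcitabine": 0.12,
            "ifosfamide": 0.12, "liposomal_doxorubicin": "<0.01",
            "trofosfamide": "<0.01", "trabectedin": 0.26,
        },
        "trabectedin": {
            "docetaxel": "<0.01", "doxorubicin_ifosfamide": "<0.01",
            "doxorubicin": "<0.01", "gemcitabine_docetaxel": 0.44,
            "ifosfamide_epirubicin": "<0.01", "ifosfamide": 0.56,
            "trofosfamide_etoposide": "<0.01",
        },
    },
    "sweden": {
        "doxorubicin_ifosfamide": {
            "cyvadic": 0.10, "gemcitabine_dacarbazine": "<0.01",
            "gemcitabine_docetaxel": 0.48, "gemcitabine_paclitaxel": "<0.01",
            "gemcitabine_vinorelbine": "<0.01", "gemcitabine": "<0.01",
            "ifosfamide": "<0.01", "liposomal_doxorubicin": "<0.01",
            "trofosfamide": 0.12, "trabectedin": 0.30,
        },
        "trabectedin": {
            "docetaxel": "<0.01", "doxorubicin_ifosfamide": 0.67,
            "doxorubicin": "<0.01", "gemcitabine_docetaxel": 0.25,
            "ifosfamide_epirubicin": "<0.01", "ifosfamide": "<0.01",
            "trofosfamide_etoposide": 0.08,
        },
    },
}

# country -> resource -> (unit, cost, vial_strength_mg or None)
COSTS = {
    "italy": [
        ("biopsy", "per procedure", 129.1, None),
        ("chest_xray", "per scan", 16.2, None),
        ("ct_scan", "per scan", 86.3, None),
        ("echocardiography", "per assessment", 51.7, None),
        ("haematology_tests", "per panel", 3.7, None),
        ("hospitalisation_day", "per day", 238.3, None),
        ("liver_function_test", "per test", 9.2, None),
        ("manage_anaemia", "per episode", 1354.8, None),
        ("manage_febrile_neutropenia", "per episode", 3305.0, None),
        ("manage_neutropenia", "per episode", 523.3, None),
        ("manage_thrombocytopenia", "per episode", 1354.8, None),
        ("mdt_assessment", "per assessment", 48.7, None),
        ("mri_scan", "per scan", 285.8, None),
        ("oncologist_visit", "per visit", 21.6, None),
        ("outpatient_attendance", "per attendance", 122.8, None),
        ("palliative_care", "per patient", 3265.0, None),
        ("pet_scan", "per scan", 1071.7, None),
        ("radiotherapist_visit", "per visit", 21.6, None),
        ("renal_function_test", "per test", 5.0, None),
        ("ultrasound", "per scan", 17.6, None),
        ("urinalysis", "per test", 6.1, None),
        # premedication products
        ("granisetron_pack", "per pack (1 mg x 10)", 133.9, None),
        ("ondansetron_pack", "per pack (4 mg x 6)", 57.8, None),
        ("dexamethasone_pack", "per pack (0.75 mg x 10)", 1.1, None),
        ("filgrastim_6mg", "per dose", 149.8, None),
        # cytotoxic vials
        ("docetaxel", "per vial", 84.4, 10),
        ("doxorubicin", "per vial", 119.5, 50),
        ("epirubicin", "per vial", 81.2, 50),
        ("gemcitabine", "per vial", 113.2, 1000),
        ("ifosfamide", "per vial", 30.7, 1000),
        ("liposomal_doxorubicin", "per vial", 548.2, 2),
        ("mesna", "per vial", 25.7, 6000),
        ("trabectedin", "per vial", 2970.1, 1),
    ],
    "spain": [
        ("biopsy", "per procedure", 603.7, None),
        ("bone_scintigraphy", "per scan", 296.8, None),
        ("chest_xray", "per scan", 6.5, None),
        ("ct_scan", "per scan", 87.5, None),
        ("echocardiography", "per assessment", 18.2, None),
        ("haematology_tests", "per panel", 20.5, None),
        ("hospitalisation_day", "per day", 212.9, None),
        ("liver_function_test", "per test", 11.7, None),
        ("manage_anaemia", "per episode", 900.0, None),
        ("manage_febrile_neutropenia", "per episode", 3829.5, None),
        ("manage_neutropenia", "per episode", 2086.1, None),
        ("manage_thrombocytopenia", "per episode", 900.0, None),
        ("mdt_assessment", "per assessment", 61.3, None),
        ("mri_scan", "per scan", 168.0, None),
        ("oncologist_visit", "per visit", 61.5, None),
        ("outpatient_attendance", "per attendance", 98.9, None),
        ("palliative_care", "per patient", 2167.7, None),
        ("pet_scan", "per scan", 500.0, None),
        ("radiotherapist_visit", "per visit", 61.5, None),
        ("renal_function_test", "per test", 8.9, None),
        ("ultrasound", "per scan", 18.2, None),
        ("urinalysis", "per test", 1.8, None),
        ("palonosetron_250mcg", "per vial", 104.6, None),
        ("aprepitant_125mg", "per dose", 90.9, None),
        ("granisetron_pack", "per pack (1 mg x 10)", 48.1, None),
        ("metoclopramide_250ml", "per bottle", 2.7, None),
        ("ondansetron_pack", "per pack (4 mg x 15)", 36.3, None),
        ("dexamethasone_pack", "per pack (1 mg x 30)", 3.0, None),
        ("diphenhydramine_pack", "per pack (25 mg x 25)", 1.4, None),
        ("pegfilgrastim_syringe", "per syringe", 1062.6, None),
        ("dacarbazine", "per vial", 21.7, 1000),
        ("docetaxel", "per vial", 182.8, 100),
        ("doxorubicin", "per vial", 4.1, 50),
        ("gemcitabine", "per vial", 75.7, 1000),
        ("ifosfamide", "per vial", 19.7, 1000),
        ("mesna", "per vial", 13.2, 3000),
        ("paclitaxel", "per vial", 83.8, 30),
        ("trabectedin", "per vial", 2049.9, 1),
        ("vinorelbine", "per vial (1 mL)", 24.1, 10),
    ],
    "sweden": [
        ("biopsy", "per procedure", 314.1, None),
        ("chest_xray", "per scan", 48.7, None),
        ("ct_scan", "per scan", 313.6, None),
        ("echocardiography", "per assessment", 214.9, None),
        ("electrocardiogram", "per test", 334.2, None),
        ("haematology_tests", "per panel", 5.2, None),
        ("hospitalisation_day", "per day", 288.6, None),
        ("manage_anaemia", "per episode", 548.6, None),
        ("manage_febrile_neutropenia", "per episode", 2892.0, None),
        ("manage_thrombocytopenia", "per episode", 548.6, None),
        ("mdt_assessment", "per assessment", 1816.5, None),
        ("mri_scan", "per scan", 386.4, None),
        ("oncologist_visit", "per visit", 283.7, None),
        ("outpatient_attendance", "per attendance", 288.6, None),
        ("palliative_care", "per patient", 1343.9, None),
        ("pet_scan", "per scan", 314.1, None),
        ("urinalysis", "per test", 20.9, None),
        ("betamethasone_8mg", "per dose", 3.2, None),
        ("tropisetron_5mg", "per dose", 20.5, None),
        ("betapred_4mg", "per dose", 6.4, None),
        ("aprepitant_125mg", "per dose", 63.8, None),
        ("pegfilgrastim_syringe", "per syringe", 1322.5, None),
        ("cyclophosphamide", "per vial", 4.1, 200),
        ("dacarbazine", "per vial", 8.9, 200),
        ("docetaxel", "per vial", 403.1, 80),
        ("doxorubicin", "per vial", 59.8, 50),
        ("etoposide", "per vial", 20.8, 100),
        ("gemcitabine", "per vial", 104.6, 1000),
        ("ifosfamide", "per vial", 65.7, 2000),
        ("mesna", "per vial", 192.2, 5000),
        ("trabectedin", "per vial", 1913.3, 1),
        ("trofosfamide", "per unit (50 mg/m2)", 1.4, 90),
        ("vincristine", "per vial", 16.2, 1),
        ("vinorelbine", "per vial (1 mL)", 24.1, 10),
    ],
}

# Monthly cancer-mortality hazards calibrated so modelled two-year death
# probabilities land in the published 0.39-0.47 band (approximations; the
# published survival curves are not tabulated).
HAZARDS = [
    ("doxorubicin_ifosfamide", "first", 0.042),
    ("trabectedin", "first", 0.032),
    ("docetaxel", "second", 0.036),
    ("gemcitabine", "second", 0.046),
    ("gemcitabine_vinorelbine", "second", 0.042),
    ("ifosfamide", "second", 0.032),
    ("trabectedin", "second", 0.031),
]

# country-specific base admission length for the doxorubicin/ifosfamide
# infusion (days per cycle), per the published one-way-analysis base values
DOXIFOS_ADMISSION = {"italy": 3.0, "spain": 4.0, "sweden": 3.0}

# Resource-use profiles: mid-range point estimates from the clinician
# interview ranges; premedication lists are country specific.
COMMON_RU = {
    "bsa_m2": 1.8,
    "diagnosis": {
        "visits": {"oncologist_visit": 3, "mdt_assessment": 1},
        "tests": {
            "haematology_tests": 1.0,
            "urinalysis": 1.0,
            "biopsy": 0.75,
            "ct_scan": 0.875,
            "mri_scan": 0.60,
            "pet_scan": 0.20,
            "chest_xray": 0.15,
            "ultrasound": 0.275,
        },
    },
    "evaluation_tests": {
        "haematology_tests": 1.0,
        "ct_scan": 0.80,
        "mri_scan": 0.30,
        "pet_scan": 0.10,
        "ultrasound": 0.10,
        "chest_xray": 0.08,
    },
    "per_cycle_tests": {
        "all": {"haematology_tests": 1.0, "renal_function_test": 1.0},
        "conditional": [
            {"condition": "contains:trabectedin", "tests": {"liver_function_test": 1.0}},
        ],
    },
    "per_course_tests": [
        {
            "condition": "contains_any:doxorubicin,epirubicin,liposomal_doxorubicin",
            "tests": {"echocardiography": 1.0},
        },
    ],
    "followup": {
        "interval_months": 4.5,
        "tests": {
            "haematology_tests": 1.0,
            "ct_scan": 0.75,
            "mri_scan": 0.375,
            "pet_scan": 0.125,
            "chest_xray": 0.08,
            "ultrasound": 0.005,
        },
        "visits": {"oncologist_visit": 1, "radiotherapist_visit": 1},
    },
    "dose_reduction": {"uptake": 0.18, "magnitude": 0.23, "from_course_cycle": 4},
    "palliative": {"one_off": True},
}

PREMEDS = {
    "italy": [
        {"cost_key": "granisetron_pack", "quantity": 0.3, "proportion": 0.5, "condition": "all"},
        {"cost_key": "ondansetron_pack", "quantity": 0.3333, "proportion": 0.5, "condition": "all"},
        {"cost_key": "dexamethasone_pack", "quantity": 1.3333, "proportion": 1.0, "condition": "all"},
    ],
    "spain": [
        {"cost_key": "palonosetron_250mcg", "quantity": 4.0, "proportion": 0.2, "condition": "all"},
        {"cost_key": "aprepitant_125mg", "quantity": 1.0, "proportion": 1.0, "condition": "not_contains:trabectedin"},
        {"cost_key": "granisetron_pack", "quantity": 0.2, "proportion": 0.2, "condition": "all"},
        {"cost_key": "metoclopramide_250ml", "quantity": 1.0, "proportion": 0.2, "condition": "all"},
        {"cost_key": "ondansetron_pack", "quantity": 0.2667, "proportion": 0.2, "condition": "all"},
        {"cost_key": "dexamethasone_pack", "quantity": 0.4, "proportion": 1.0, "condition": "all"},
        {"cost_key": "diphenhydramine_pack", "quantity": 0.24, "proportion": 1.0, "condition": "contains_any:paclitaxel,docetaxel,trabectedin"},
    ],
    "sweden": [
        {"cost_key": "betamethasone_8mg", "quantity": 1.0, "proportion": 1.0, "condition": "not_contains:trabectedin"},
        {"cost_key": "tropisetron_5mg", "quantity": 1.0, "proportion": 1.0, "condition": "not_contains:trabectedin"},
        {"cost_key": "betapred_4mg", "quantity": 2.0, "proportion": 1.0, "condition": "contains:trabectedin"},
    ],
}

GCSF = {
    "italy": {"cost_key": "filgrastim_6mg", "quantity": 1.0},
    "spain": {"cost_key": "pegfilgrastim_syringe", "quantity": 1.0},
    "sweden": {"cost_key": "pegfilgrastim_syringe", "quantity": 1.0},
}
GCSF_UPTAKE = [
    {"condition": "regimen:doxorubicin_ifosfamide", "proportion": 0.65},
    {"condition": "contains:gemcitabine", "proportion": 0.15},
]

CONSTANTS = {
    "cycle_length_months": 1,
    "horizon_cycles": 24,
    "discount_rate": 0.03,
    "first_line_switch_cycle": 3,
    "second_line_eval_cycles": 3,
    "mean_course_cycles": 6,
    "psa_iterations": 10000,
    "dsa_fraction": 0.20,
    "ceac_reference_threshold": 35000,
}
UTILITIES = {"cr": 0.60, "pr": 0.51, "sd": 0.43, "pd": 0.30}

LIFE_TABLE = [(age, round(min(0.02 * 1.1 ** (age - 65), 1.0), 6)) for age in range(65, 91)]


def write_csv(path, header, rows):
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def main():
    common = ROOT / "_common"
    write_csv(
        common / "efficacy.csv",
        ["regimen", "line", "p_cr", "p_pr", "p_sd", "p_pd", "dur_cr", "dur_pr", "dur_sd", "imputed_probs", "imputed_durs"],
        [list(r) for r in EFFICACY],
    )
    write_csv(
        common / "toxicity.csv",
        ["regimen", "line", "p_neutropenia", "p_febrile_neutropenia", "p_thrombocytopenia", "p_anaemia", "imputed"],
        [list(r) for r in TOXICITY],
    )
    write_csv(
        common / "hazards.csv",
        ["regimen", "line", "rate_per_month"],
        [list(r) for r in HAZARDS],
    )
    write_csv(
        common / "life_table.csv",
        ["age", "annual_mortality"],
        [list(r) for r in LIFE_TABLE],
    )

    for country in ("italy", "spain", "sweden"):
        cdir = ROOT / country
        cdir.mkdir(parents=True, exist_ok=True)
        write_csv(
            cdir / "regimens.csv",
            ["regimen", "drug", "dose_per_m2_mg", "admission_days", "outpatient_attendances", "oral", "line"],
            [
                [name, drug, dose,
                 DOXIFOS_ADMISSION[country] if name == "doxorubicin_ifosfamide" else adm,
                 outp, oral, line]
                for name, comps, adm, outp, oral, line in REGIMENS
                for drug, dose in comps
            ],
        )
        write_csv(
            cdir / "mixes.csv",
            ["first_line", "second_line", "probability"],
            [
                [fl, sl, p]
                for fl, entries in MIXES[country].items()
                for sl, p in entries.items()
            ],
        )
        write_csv(
            cdir / "costs.csv",
            ["resource", "unit", "cost_eur", "vial_strength_mg"],
            [
                [key, unit, cost, "" if strength is None else strength]
                for key, unit, cost, strength in COSTS[country]
            ],
        )
        ru = dict(COMMON_RU)
        ru = {
            **COMMON_RU,
            "premedication": PREMEDS[country],
            "gcsf": {**GCSF[country], "uptake": GCSF_UPTAKE},
        }
        if country == "sweden":
            # no renal-function tariff in the Swedish cost list; the bundle
            # key simply prices at zero, so the common profile is reused
            pass
        with (cdir / "resource_use.yaml").open("w") as fh:
            yaml.safe_dump(ru, fh, sort_keys=False)
        with (cdir / "constants.yaml").open("w") as fh:
            yaml.safe_dump(
                {"country": country, "utilities": UTILITIES, **CONSTANTS},
                fh,
                sort_keys=False,
            )
    print("packs written to", ROOT)


if __name__ == "__main__":
    main()
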