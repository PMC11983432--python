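"""Published VigiAccess summary counts for three androgen antagonists.

These are the aggregate numbers displayed by WHO-VigiAccess (retrieved
early 2025) for apalutamide, darolutamide and enzalutamide: report-level
demographic distributions, reaction-level SOC incidence, top-20 PT report
rates, and the shared/drug-exclusive PT-level signal lists.  Record-level
data is not publicly downloadable, so these printed aggregates serve as
regression fixtures for the percentage, profiling and comparison logic.

Notes on the source data
------------------------
* Demographic columns sum exactly to the per-drug report totals; SOC
  columns sum exactly to the reaction totals for apalutamide and
  darolutamide, and to N-2 for enzalutamide (the pregnancy/puerperium SOC,
  excluded from the 26 analyzed SOCs, holds the remainder).
* Four printed SOC percentages are internally inconsistent with their own
  numerator/denominator (off by +0.01 under any standard rounding); they
  are pinned in :data:`PERCENT_ERRATA`.
* The shared-signal table prints per-SOC signal counts summing to the
  stated 162 total, but its "General disorders" ADR list carries 26 entries
  against a printed count of 25; pinned in :data:`SHARED_COUNT_ERRATA`.
"""

from __future__ import annotations

from .compare import SignalSet
from .models import MeddraMap
from .profiles import SocProfile, StratifiedCounts

DRUGS = ("apalutamide", "darolutamide", "enzalutamide")

#: Report-level totals (number of ADR reports per drug).
REPORT_COUNTS = {"apalutamide": 11_452, "darolutamide": 2_269, "enzalutamide": 53_007}

#: Reaction-level totals (number of reported ADRs, the N of the SOC table).
REACTION_TOTALS = {"apalutamide": 20_965, "darolutamide": 5_236, "enzalutamide": 145_819}

#: Reported serious-AE rates (%), printed against the reaction-level N.
#: The underlying outcome counts are not published, so these are display
#: values only and are not regression targets.
SERIOUS_RATES = {"apalutamide": 4.94, "darolutamide": 2.85, "enzalutamide": 5.06}

# axis -> drug -> list of (stratum label, count, printed percent)
DEMOGRAPHICS: dict[str, dict[str, list[tuple[str, int, str]]]] = {
    "sex": {
        "apalutamide": [("Female", 35, "0.31"), ("Male", 10_751, "93.88"), ("Unknown", 666, "5.82")],
        "darolutamide": [("Female", 7, "0.31"), ("Male", 2_124, "93.61"), ("Unknown", 138, "6.08")],
        "enzalutamide": [("Female", 313, "0.59"), ("Male", 51_764, "97.66"), ("Unknown", 930, "1.75")],
    },
    "age_group": {
        "apalutamide": [
            ("<18", 3, "0.03"),
            ("18-44", 10, "0.09"),
            ("45-64", 722, "6.30"),
            ("65-74", 2_217, "19.36"),
            (">=75", 3_624, "31.65"),
            ("Unknown", 4_876, "42.58"),
        ],
        "darolutamide": [
            ("<18", 2, "0.09"),
            ("18-44", 3, "0.13"),
            ("45-64", 262, "11.55"),
            ("65-74", 495, "21.82"),
            (">=75", 777, "34.24"),
            ("Unknown", 730, "32.17"),
        ],
        "enzalutamide": [
            ("<18", 7, "0.01"),
            ("18-44", 58, "0.11"),
            ("45-64", 4_091, "7.72"),
            ("65-74", 9_422, "17.78"),
            (">=75", 17_308, "32.65"),
            ("Unknown", 22_121, "41.73"),
        ],
    },
    "continent": {
        "apalutamide": [
            ("Africa", 141, "1.23"),
            ("Americas", 5_932, "51.80"),
            ("Asia", 1_639, "14.31"),
            ("Europe", 3_724, "32.52"),
            ("Oceania", 16, "0.14"),
        ],
        "darolutamide": [
            ("Africa", 0, "0.00"),
            ("Americas", 1_127, "49.67"),
            ("Asia", 368, "16.22"),
            ("Europe", 718, "31.64"),
            ("Oceania", 56, "2.47"),
        ],
        "enzalutamide": [
            ("Africa", 65, "0.12"),
            ("Americas", 42_759, "80.67"),
            ("Asia", 4_220, "7.96"),
            ("Europe", 5_648, "10.66"),
            ("Oceania", 315, "0.59"),
        ],
    },
    "year": {
        "apalutamide": [
            ("Before 2017", 3, "0.03"),
            ("2017", 4, "0.03"),
            ("2018", 75, "0.65"),
            ("2019", 844, "7.37"),
            ("2020", 1_091, "9.53"),
            ("2021", 1_317, "11.50"),
            ("2022", 2_191, "19.13"),
            ("2023", 2_385, "20.83"),
            ("2024", 3_542, "30.93"),
        ],
        "darolutamide": [
            ("Before 2017", 2, "0.09"),
            ("2017", 2, "0.09"),
            ("2018", 0, "0.00"),
            ("2019", 11, "0.48"),
            ("2020", 97, "4.28"),
            ("2021", 242, "10.67"),
            ("2022", 336, "14.81"),
            ("2023", 580, "25.56"),
            ("2024", 999, "44.03"),
        ],
        "enzalutamide": [
            ("Before 2017", 14_551, "27.45"),
            ("2017", 8_209, "15.49"),
            ("2018", 10_471, "19.75"),
            ("2019", 7_789, "14.69"),
            ("2020", 2_094, "3.95"),
            ("2021", 2_238, "4.22"),
            ("2022", 2_140, "4.04"),
            ("2023", 2_361, "4.45"),
            ("2024", 3_154, "5.95"),
        ],
    },
}

#: The 26 analyzed system organ classes, in the published display order,
#: with per-drug (reaction count, printed percent).
SOC_TABLE: list[tuple[str, dict[str, tuple[int, str]]]] = [
    ("Blood and lymphatic system disorders", {"apalutamide": (280, "1.34"), "darolutamide": (113, "2.16"), "enzalutamide": (1_205, "0.83")}),
    ("Cardiac disorders", {"apalutamide": (486, "2.32"), "darolutamide": (119, "2.27"), "enzalutamide": (2_241, "1.54")}),
    ("Congenital, familial and genetic disorders", {"apalutamide": (7, "0.03"), "darolutamide": (1, "0.02"), "enzalutamide": (30, "0.02")}),
    ("Ear and labyrinth disorders", {"apalutamide": (90, "0.43"), "darolutamide": (22, "0.42"), "enzalutamide": (715, "0.49")}),
    ("Endocrine disorders", {"apalutamide": (195, "0.93"), "darolutamide": (5, "0.10"), "enzalutamide": (98, "0.07")}),
    ("Eye disorders", {"apalutamide": (133, "0.63"), "darolutamide": (55, "1.05"), "enzalutamide": (1_661, "1.14")}),
    ("Gastrointestinal disorders", {"apalutamide": (1_328, "6.33"), "darolutamide": (469, "8.96"), "enzalutamide": (14_604, "10.02")}),
    ("General disorders and administration site conditions", {"apalutamide": (3_835, "18.29"), "darolutamide": (992, "18.95"), "enzalutamide": (35_797, "24.55")}),
    ("Hepatobiliary disorders", {"apalutamide": (103, "0.49"), "darolutamide": (85, "1.62"), "enzalutamide": (461, "0.32")}),
    ("Immune system disorders", {"apalutamide": (83, "0.40"), "darolutamide": (19, "0.36"), "enzalutamide": (328, "0.23")}),
    ("Infections and infestations", {"apalutamide": (586, "2.80"), "darolutamide": (142, "2.71"), "enzalutamide": (4_007, "2.75")}),
    ("Injury, poisoning and procedural complications", {"apalutamide": (1_443, "6.88"), "darolutamide": (366, "6.99"), "enzalutamide": (10_731, "7.36")}),
    ("Investigations", {"apalutamide": (1_482, "7.07"), "darolutamide": (512, "9.78"), "enzalutamide": (10_219, "7.01")}),
    ("Metabolism and nutrition disorders", {"apalutamide": (447, "2.13"), "darolutamide": (111, "2.12"), "enzalutamide": (4_709, "3.23")}),
    ("Musculoskeletal and connective tissue disorders", {"apalutamide": (973, "4.64"), "darolutamide": (370, "7.07"), "enzalutamide": (10_467, "7.18")}),
    ("Neoplasms benign, malignant and unspecified (incl cysts and polyps)", {"apalutamide": (604, "2.88"), "darolutamide": (246, "4.70"), "enzalutamide": (7_216, "4.95")}),
    ("Nervous system disorders", {"apalutamide": (1_495, "7.13"), "darolutamide": (433, "8.27"), "enzalutamide": (15_569, "10.68")}),
    ("Psychiatric disorders", {"apalutamide": (514, "2.45"), "darolutamide": (147, "2.81"), "enzalutamide": (5_887, "4.04")}),
    ("Renal and urinary disorders", {"apalutamide": (326, "1.56"), "darolutamide": (127, "2.43"), "enzalutamide": (2_645, "1.81")}),
    ("Reproductive system and breast disorders", {"apalutamide": (132, "0.63"), "darolutamide": (57, "1.09"), "enzalutamide": (785, "0.54")}),
    ("Respiratory, thoracic and mediastinal disorders", {"apalutamide": (574, "2.74"), "darolutamide": (172, "3.29"), "enzalutamide": (4_407, "3.02")}),
    ("Skin and subcutaneous tissue disorders", {"apalutamide": (4_078, "19.45"), "darolutamide": (369, "7.05"), "enzalutamide": (4_196, "2.88")}),
    ("Social circumstances", {"apalutamide": (40, "0.19"), "darolutamide": (17, "0.33"), "enzalutamide": (356, "0.24")}),
    ("Surgical and medical procedures", {"apalutamide": (594, "2.83"), "darolutamide": (83, "1.59"), "enzalutamide": (1_208, "0.83")}),
    ("Vascular disorders", {"apalutamide": (1_056, "5.04"), "darolutamide": (199, "3.80"), "enzalutamide": (4_884, "3.35")}),
    ("Product issues", {"apalutamide": (81, "0.39"), "darolutamide": (5, "0.10"), "enzalutamide": (1_391, "0.95")}),
]

SOC_LIST = tuple(soc for soc, _ in SOC_TABLE)

#: Printed percent cells that do not recompute from their own numerator and
#: denominator under half-up (or any standard) rounding; values are
#: (printed, recomputed).  Source display errors, kept for transparency.
PERCENT_ERRATA = {
    ("soc", "darolutamide", "Respiratory, thoracic and mediastinal disorders"): ("3.29", "3.28"),
    ("soc", "darolutamide", "Social circumstances"): ("0.33", "0.32"),
    ("soc", "apalutamide", "Renal and urinary disorders"): ("1.56", "1.55"),
    ("soc", "enzalutamide", "Immune system disorders"): ("0.23", "0.22"),
}

#: Top-20 PTs per drug with their printed report rates (%, reaction-level N).
TOP20: dict[str, list[tuple[str, str]]] = {
    "apalutamide": [
        ("Rash", "9.93"), ("Fatigue", "4.25"), ("Death", "4.17"), ("Hot flush", "2.59"),
        ("Product dose omission issue", "1.77"), ("Diarrhoea", "1.72"), ("Pruritus", "1.47"),
        ("Hypertension", "1.46"), ("Arthralgia", "1.45"), ("Asthenia", "1.42"),
        ("Prostatic specific antigen increased", "1.33"), ("Dizziness", "1.23"),
        ("Off label use", "1.18"), ("Fall", "1.17"), ("Drug ineffective", "1.06"),
        ("Decreased appetite", "1.01"), ("Nausea", "0.94"), ("Rash pruritic", "0.88"),
        ("Weight decreased", "0.83"), ("Interstitial lung disease", "0.77"),
    ],
    "darolutamide": [
        ("Fatigue", "6.26"), ("Rash", "2.46"), ("Off label use", "2.39"), ("Death", "2.23"),
        ("Asthenia", "2.18"), ("Diarrhoea", "1.83"), ("Hot flush", "1.83"),
        ("Prostatic specific antigen increased", "1.53"), ("Pain in extremity", "1.45"),
        ("Nausea", "1.43"), ("Dizziness", "1.28"), ("Arthralgia", "1.20"), ("Dyspnoea", "1.15"),
        ("Decreased appetite", "1.07"), ("Neuropathy peripheral", "1.03"),
        ("Product dose omission issue", "0.94"), ("Hormone-refractory prostate cancer", "0.94"),
        ("Hypertension", "0.90"), ("Prostate cancer", "0.84"), ("Peripheral swelling", "0.78"),
    ],
    "enzalutamide": [
        ("Fatigue", "6.34"), ("Death", "4.75"), ("Malignant neoplasm progression", "3.37"),
        ("Drug ineffective", "2.63"), ("Prostatic specific antigen increased", "2.53"),
        ("Asthenia", "2.48"), ("Decreased appetite", "2.09"), ("Nausea", "2.06"),
        ("Hot flush", "1.98"), ("Dizziness", "1.86"), ("Diarrhoea", "1.72"), ("Back pain", "1.35"),
        ("Underdose", "1.34"), ("Arthralgia", "1.22"), ("Constipation", "1.05"),
        ("Headache", "1.04"), ("Weight decreased", "1.03"), ("Fall", "1.02"),
        ("Pain", "0.94"), ("Malaise", "0.87"),
    ],
}

#: PT-level signals shared by all three drugs, grouped by SOC:
#: (SOC, verbatim ADR list, printed signal count).
SHARED_SIGNALS: list[tuple[str, tuple[str, ...], int]] = [
    (
        "General disorders and administration site conditions",
        ("Peripheral swelling", "Gait inability", "Pyrexia", "Disease progression", "Oedema",
         "Chest discomfort", "Swelling face", "Chest pain", "Asthenia", "Adverse drug reaction",
         "Drug ineffective", "Drug intolerance", "Gait disturbance", "Death",
         "General physical health deterioration", "Oedema peripheral", "Pain", "Drug interaction",
         "Condition aggravated", "Chills", "Malaise", "Fatigue", "Illness", "Feeling hot",
         "Feeling abnormal", "Adverse event"),
        25,
    ),
    (
        "Nervous system disorders",
        ("Taste disorder", "Transient ischaemic attack", "Dysgeusia", "Somnolence",
         "Loss of consciousness", "Hypersomnia", "Paraesthesia", "Memory impairment", "Ageusia",
         "Dementia", "Hypoaesthesia", "Headache", "Syncope", "Neuropathy peripheral", "Tremor",
         "Cognitive disorder", "Balance disorder", "Cerebrovascular accident", "Seizure",
         "Dizziness", "Lethargy"),
        21,
    ),
    (
        "Gastrointestinal disorders",
        ("Abdominal distension", "Vomiting", "Diarrhoea", "Abdominal discomfort", "Dyspepsia",
         "Abdominal pain upper", "Dry mouth", "Gastrooesophageal reflux disease",
         "Gastrointestinal disorder", "Nausea", "Abdominal pain", "Flatulence", "Dysphagia",
         "Constipation"),
        14,
    ),
    (
        "Musculoskeletal and connective tissue disorders",
        ("Joint swelling", "Arthralgia", "Bone pain", "Limb discomfort", "Back pain",
         "Mobility decreased", "Muscle atrophy", "Pain in extremity", "Myalgia",
         "Musculoskeletal pain", "Muscle spasms", "Muscular weakness", "Arthritis"),
        13,
    ),
    (
        "Skin and subcutaneous tissue disorders",
        ("Erythema", "Urticaria", "Alopecia", "Dry skin", "Night sweats", "Rash pruritic",
         "Pruritus", "Skin exfoliation", "Rash", "Hyperhidrosis"),
        10,
    ),
    (
        "Injury, poisoning and procedural complications",
        ("Product use in unapproved indication", "Fracture", "Off label use", "Hip fracture",
         "Incorrect dose administered", "Fall", "Wrong technique in product usage process",
         "Inappropriate schedule of product administration", "Product dose omission issue"),
        9,
    ),
    (
        "Investigations",
        ("Weight decreased", "Prostatic specific antigen increased", "Blood glucose increased",
         "Blood pressure decreased", "Blood pressure increased", "Heart rate increased",
         "Weight increased", "White blood cell count decreased", "Haemoglobin decreased"),
        9,
    ),
    (
        "Infections and infestations",
        ("Nasopharyngitis", "Urinary tract infection", "Pneumonia", "Herpes zoster", "Influenza",
         "Infection", "Sepsis", "COVID-19"),
        8,
    ),
    (
        "Renal and urinary disorders",
        ("Renal impairment", "Acute kidney injury", "Dysuria", "Haematuria", "Pollakiuria",
         "Urinary retention", "Nocturia", "Renal failure"),
        8,
    ),
    (
        "Psychiatric disorders",
        ("Insomnia", "Hallucination", "Anxiety", "Depression", "Eating disorder",
         "Confusional state", "Sleep disorder"),
        7,
    ),
    (
        "Respiratory, thoracic and mediastinal disorders",
        ("Oropharyngeal pain", "Dyspnoea", "Pulmonary embolism", "Interstitial lung disease",
         "Epistaxis", "Dyspnoea exertional", "Cough"),
        7,
    ),
    (
        "Cardiac disorders",
        ("Cardiac failure", "Cardiac failure congestive", "Cardiac disorder", "Cardiac arrest",
         "Myocardial infarction", "Atrial fibrillation"),
        6,
    ),
    (
        "Neoplasms benign, malignant and unspecified (incl cysts and polyps)",
        ("Metastases to bone", "Hormone-refractory prostate cancer", "Prostate cancer",
         "Prostate cancer metastatic", "Malignant neoplasm progression", "Neoplasm malignant"),
        6,
    ),
    (
        "Vascular disorders",
        ("Hot flush", "Blood pressure fluctuation", "Hypertension", "Thrombosis", "Hypotension"),
        5,
    ),
    ("Blood and lymphatic system disorders", ("Neutropenia", "Anaemia", "Thrombocytopenia"), 3),
    ("Ear and labyrinth disorders", ("Tinnitus", "Vertigo"), 2),
    ("Eye disorders", ("Visual impairment", "Vision blurred"), 2),
    ("Metabolism and nutrition disorders", ("Dehydration", "Decreased appetite"), 2),
    ("Reproductive system and breast disorders", ("Gynaecomastia", "Erectile dysfunction"), 2),
    ("Hepatobiliary disorders", ("Hepatic function abnormal",), 1),
    ("Immune system disorders", ("Hypersensitivity",), 1),
    ("Surgical and medical procedures", ("Hospitalisation",), 1),
]

#: Rows whose printed signal count disagrees with the length of the listed
#: ADRs; values are (listed, printed).  The printed counts sum to the
#: stated 162 shared signals, so the count column is taken as authoritative.
SHARED_COUNT_ERRATA = {
    "General disorders and administration site conditions": (26, 25),
}

#: Drug-exclusive PT-level signals: SOC -> drug -> PT tuple.
UNIQUE_SIGNALS: dict[str, dict[str, tuple[str, ...]]] = {
    "Blood and lymphatic system disorders": {
        "apalutamide": ("Eosinophilia", "Agranulocytosis"),
        "darolutamide": ("Myelosuppression", "Disseminated intravascular coagulation", "Cytopenia", "Blood disorder"),
    },
    "Cardiac disorders": {
        "apalutamide": ("Myocardial ischaemia", "Acute myocardial infarction"),
        "darolutamide": ("Cardiotoxicity", "Bradycardia"),
    },
    "Endocrine disorders": {"apalutamide": ("Hypothyroidism", "Thyroid disorder")},
    "Eye disorders": {"darolutamide": ("Blindness",), "enzalutamide": ("Cataract",)},
    "Gastrointestinal disorders": {
        "apalutamide": ("Rectal haemorrhage",),
        "darolutamide": ("Faeces soft", "Frequent bowel movements", "Colitis", "Faeces discoloured", "Gastrointestinal motility disorder", "Swollen tongue"),
        "enzalutamide": ("Retching", "Gastrointestinal haemorrhage"),
    },
    "General disorders and administration site conditions": {
        "apalutamide": ("Therapeutic product effect decreased",),
        "darolutamide": ("Pre-existing condition improved", "Feeling cold", "Exercise tolerance decreased"),
        "enzalutamide": ("Treatment failure", "Influenza like illness"),
    },
    "Hepatobiliary disorders": {
        "darolutamide": ("Hepatic cytolysis", "Hypertransaminasaemia", "Hepatitis"),
    },
    "Infections and infestations": {
        "apalutamide": ("Lower respiratory tract infection",),
        "darolutamide": ("Escherichia infection",),
    },
    "Injury, poisoning and procedural complications": {
        "apalutamide": ("Incorrect dosage administered", "Intentional product use issue"),
        "darolutamide": ("Limb injury", "Toxicity to various agents", "Incorrect product administration duration", "Multiple fractures", "Product prescribing issue", "Product dose omission in error", "Accidental exposure to product", "Nerve injury"),
        "enzalutamide": ("Product storage error", "Intentional product misuse", "Overdose", "Underdose", "Circumstance or information capable of leading to medication error", "Intentional dose omission", "Foreign body in throat"),
    },
    "Investigations": {
        "apalutamide": ("Glycosylated haemoglobin increased", "Blood potassium increased", "Blood triglycerides increased", "Blood thyroid stimulating hormone increased", "Laboratory test abnormal", "Prostatic specific antigen decreased"),
        "darolutamide": ("Blood sodium decreased", "Blood calcium decreased", "Red blood cell count decreased", "Transaminases increased", "Blood bilirubin increased", "Heart rate decreased", "International normalised ratio increased", "Blood potassium decreased", "Blood testosterone decreased"),
        "enzalutamide": ("Full blood count decreased",),
    },
    "Metabolism and nutrition disorders": {
        "apalutamide": ("Hyperkalaemia", "Hypercholesterolaemia"),
        "darolutamide": ("Increased appetite",),
        "enzalutamide": ("Hypophagia",),
    },
    "Musculoskeletal and connective tissue disorders": {
        "apalutamide": ("Osteoporosis",),
        "darolutamide": ("Rhabdomyolysis", "Musculoskeletal discomfort", "Musculoskeletal disorder", "Groin pain"),
    },
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)": {
        "apalutamide": ("Lung neoplasm malignant",),
        "darolutamide": ("Bladder cancer", "Neoplasm progression", "Metastases to spine", "Metastases to pelvis", "Malignant melanoma"),
    },
    "Nervous system disorders": {
        "apalutamide": ("Sensory disturbance", "Cerebral infarction"),
        "darolutamide": ("Head discomfort", "Parkinson's disease", "Motor dysfunction", "Neuralgia", "Presyncope"),
        "enzalutamide": ("Dyskinesia",),
    },
    "Product issues": {
        "apalutamide": ("Product label issue", "Product packaging quantity issue"),
        "enzalutamide": ("Product availability issue", "Product physical issue"),
    },
    "Psychiatric disorders": {
        "darolutamide": ("Poor quality sleep", "Delirium", "Apathy", "Stress", "Personality change"),
        "enzalutamide": ("Disorientation", "Restlessness"),
    },
    "Renal and urinary disorders": {
        "apalutamide": ("Micturition urgency",),
        "darolutamide": ("Urinary tract disorder",),
    },
    "Reproductive system and breast disorders": {
        "apalutamide": ("Pelvic pain", "Breast enlargement"),
        "darolutamide": ("Breast swelling", "Breast pain"),
    },
    "Respiratory, thoracic and mediastinal disorders": {
        "darolutamide": ("Pulmonary hypertension", "Lung disorder", "Pneumonitis"),
        "enzalutamide": ("Choking", "Pleural effusion", "Throat irritation", "Chronic obstructive pulmonary disease", "Rhinorrhoea", "Productive cough"),
    },
    "Skin and subcutaneous tissue disorders": {
        "apalutamide": ("Lichenoid keratosis", "Skin toxicity", "Drug reaction with eosinophilia and systemic symptoms", "Erythema multiforme", "Toxic epidermal necrolysis", "Eczema", "Dermatitis allergic", "Stevens-johnson syndrome", "Toxic skin eruption", "Dermatitis", "Skin reaction", "Dermatitis exfoliative generalised"),
        "darolutamide": ("Haemorrhage subcutaneous", "Skin atrophy", "Palmar-plantar erythrodysaesthesia syndrome", "Angioedema", "Nail disorder"),
    },
    "Social circumstances": {"darolutamide": ("Bedridden",)},
    "Surgical and medical procedures": {
        "apalutamide": ("Therapy change", "Surgery"),
        "darolutamide": ("Cardiac operation",),
    },
    "Vascular disorders": {
        "darolutamide": ("Deep vein thrombosis", "Orthostatic hypotension"),
    },
}


def reference_meddra_map() -> MeddraMap:
    """PT->SOC map covering every PT in the published signal and top-20 tables.

    A toy two-level hierarchy standing in for licensed MedDRA; SOC universe
    is the 26 analyzed SOCs in display order.
    """
    pt_to_soc: dict[str, str] = {}
    for soc, pts, _ in SHARED_SIGNALS:
        for pt in pts:
            pt_to_soc[pt] = soc
    for soc, per_drug in UNIQUE_SIGNALS.items():
        for pts in per_drug.values():
            for pt in pts:
                pt_to_soc.setdefault(pt, soc)
    return MeddraMap(pt_to_soc=pt_to_soc, soc_list=SOC_LIST)


def demographic_fixture(drug: str, axis: str) -> StratifiedCounts:
    """Published demographic distribution as a StratifiedCounts instance."""
    rows = DEMOGRAPHICS[axis][drug]
    return StratifiedCounts(
        stratum_labels=tuple(label for label, _, _ in rows),
        counts=tuple(count for _, count, _ in rows),
        denominator=REPORT_COUNTS[drug],
    )


def soc_profile_fixture(drug: str) -> SocProfile:
    """Published SOC incidence profile as a SocProfile instance.

    The unmapped bucket absorbs the difference between the reaction total
    and the 26-SOC sum (non-zero only for enzalutamide, where the excluded
    pregnancy/puerperium SOC holds 2 reactions).
    """
    per_soc = {soc: cells[drug][0] for soc, cells in ((s, c) for s, c in SOC_TABLE)}
    total = REACTION_TOTALS[drug]
    return SocProfile(
        drug=drug,
        total_reactions=total,
        per_soc=per_soc,
        n_unmapped=total - sum(per_soc.values()),
    )


def reference_signal_sets() -> list[SignalSet]:
    """Per-drug signal sets reconstructed from the published shared and
    drug-exclusive signal tables.

    Each drug's set is the union of all shared PTs and its own exclusive
    PTs; pairwise-but-not-universal signals are not published and therefore
    not representable here.
    """
    shared_pairs = [(pt, soc) for soc, pts, _ in SHARED_SIGNALS for pt in pts]
    sets = []
    for drug in DRUGS:
        pairs = list(shared_pairs)
        for soc, per_drug in UNIQUE_SIGNALS.items():
            for pt in per_drug.get(drug, ()):
                pairs.append((pt, soc))
        sets.append(SignalSet.from_pairs(drug, pairs))
    return sets
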