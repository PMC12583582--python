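"""Study constants: survey summary statistics, toxicological benchmarks,
exposure profiles and isotopic end-members for the Sanandaj urban-soil survey.

Every table here is data, not behaviour: the registry in :mod:`soilrisk.core_data`
wraps these dicts with validated, provenance-tagged lookups, and all of them can
be overridden from YAML at run time.

Units: PTE concentrations mg/kg, PAH concentrations µg/kg, EC µS/cm,
exposure-profile units as annotated on each field.
"""

from __future__ import annotations

# --------------------------------------------------------------------------
# Potentially toxic elements
# --------------------------------------------------------------------------

ELEMENTS = ("Zn", "Cu", "Ni", "Pb", "Cr", "Cd", "As")

#: Survey descriptive statistics per analyte:
#: (min, max, mean, sd, cv, kurtosis, skewness).  pH is dimensionless,
#: EC in µS/cm, elements in mg/kg.
SURVEY_PTE_STATS: dict[str, tuple[float, ...]] = {
    "Zn": (74.0, 270.0, 125.55, 40.77, 0.32, 1.93, 4.46),
    "Cu": (34.0, 240.0, 56.83, 29.84, 0.52, 4.72, 6.96),
    "Ni": (37.0, 78.0, 56.19, 9.17, 0.16, 0.14, -0.32),
    "Pb": (5.0, 128.0, 27.04, 20.11, 0.74, 2.66, 10.94),
    "Cr": (72.0, 138.0, 111.47, 16.28, 0.15, -0.56, -0.49),
    "Cd": (0.19, 1.6, 0.24, 0.19, 0.77, 7.24, 52.56),
    "As": (2.6, 38.0, 4.62, 4.81, 1.04, 6.48, 44.94),
    "pH": (8.09, 8.83, 8.52, 0.16, 0.02, -0.51, -0.27),
    "EC": (223.0, 3160.0, 673.68, 557.79, 0.83, 3.32, 12.13),
}

#: Upper-continental-crust reference concentrations Cn (mg/kg), the baseline
#: against which the Hakanson risk factor is computed.
UCC_REFERENCE: dict[str, float] = {
    "Zn": 31.0, "Cu": 29.0, "Ni": 20.0, "Pb": 15.0,
    "Cr": 35.0, "Cd": 0.09, "As": 4.8,
}

#: Hakanson toxic-response factors Tr (dimensionless).  Ni is the standard
#: Hakanson value of 5.
TOXIC_RESPONSE: dict[str, float] = {
    "Zn": 1.0, "Cu": 5.0, "Ni": 5.0, "Pb": 5.0,
    "Cr": 2.0, "Cd": 30.0, "As": 10.0,
}

#: Oral / inhalation / dermal reference doses, mg/(kg·day).  These follow the
#: USEPA IRIS convention used throughout urban-soil health-risk studies and are
#: configurable defaults: hazard quotients are only as authoritative as the
#: RfD set supplied.
RFD_DEFAULTS: dict[str, dict[str, float]] = {
    "Zn": {"ingestion": 3.0e-1, "inhalation": 3.0e-1, "dermal": 6.0e-2},
    "Cu": {"ingestion": 4.0e-2, "inhalation": 4.02e-2, "dermal": 1.2e-2},
    "Ni": {"ingestion": 2.0e-2, "inhalation": 2.06e-2, "dermal": 5.4e-3},
    "Pb": {"ingestion": 3.5e-3, "inhalation": 3.52e-3, "dermal": 5.25e-4},
    "Cr": {"ingestion": 3.0e-3, "inhalation": 2.86e-5, "dermal": 6.0e-5},
    "Cd": {"ingestion": 1.0e-3, "inhalation": 1.0e-3, "dermal": 2.5e-5},
    "As": {"ingestion": 3.0e-4, "inhalation": 3.01e-4, "dermal": 1.23e-4},
}

#: Carcinogenic slope factors, (mg/(kg·day))⁻¹; elements without an accepted
#: slope factor are omitted and yield no cancer-risk estimate.
SF_DEFAULTS: dict[str, float] = {
    "Ni": 0.84, "Pb": 0.0085, "Cr": 0.5, "Cd": 6.3, "As": 1.5,
}

# --------------------------------------------------------------------------
# Polycyclic aromatic hydrocarbons
# --------------------------------------------------------------------------

#: The 15 priority PAHs tracked by the survey: ring count and whether the
#: compound is classified carcinogenic (USEPA B2 group).
PAH_COMPOUNDS: dict[str, dict] = {
    "Nap":   {"name": "Naphthalene",            "rings": 2, "carcinogenic": False},
    "Acy":   {"name": "Acenaphthylene",         "rings": 3, "carcinogenic": False},
    "Ace":   {"name": "Acenaphthene",           "rings": 3, "carcinogenic": False},
    "Flu":   {"name": "Fluorene",               "rings": 3, "carcinogenic": False},
    "Phe":   {"name": "Phenanthrene",           "rings": 3, "carcinogenic": False},
    "Ant":   {"name": "Anthracene",             "rings": 3, "carcinogenic": False},
    "Flt":   {"name": "Fluoranthene",           "rings": 4, "carcinogenic": False},
    "Pyr":   {"name": "Pyrene",                 "rings": 4, "carcinogenic": False},
    "BaA":   {"name": "Benz[a]anthracene",      "rings": 4, "carcinogenic": True},
    "BbF":   {"name": "Benzo[b]fluoranthene",   "rings": 5, "carcinogenic": True},
    "BkF":   {"name": "Benzo[k]fluoranthene",   "rings": 5, "carcinogenic": True},
    "BaP":   {"name": "Benzo[a]pyrene",         "rings": 5, "carcinogenic": True},
    "DBA":   {"name": "Dibenz[a,h]anthracene",  "rings": 5, "carcinogenic": True},
    "InP":   {"name": "Indeno[1,2,3-cd]pyrene", "rings": 6, "carcinogenic": True},
    "BghiP": {"name": "Benzo[ghi]perylene",     "rings": 6, "carcinogenic": False},
}

#: Toxicity equivalency factors as tabulated by the study (note the
#: nonstandard BaA value of 0.001).  BaP and BghiP are completed from the
#: study's text (DBA shares TEF 1 with BaP).
TEF_STUDY: dict[str, float] = {
    "Nap": 0.001, "Acy": 0.001, "Ace": 0.001, "Flu": 0.001, "Phe": 0.001,
    "Ant": 0.01, "Flt": 0.01, "Pyr": 0.001, "BaA": 0.001, "BbF": 0.1,
    "BkF": 0.1, "BaP": 1.0, "InP": 0.1, "DBA": 1.0, "BghiP": 0.01,
}

#: The standard Nisbet & LaGoy TEF set, selectable as an alternative.
TEF_NISBET_LAGOY: dict[str, float] = {
    "Nap": 0.001, "Acy": 0.001, "Ace": 0.001, "Flu": 0.001, "Phe": 0.001,
    "Ant": 0.01, "Flt": 0.001, "Pyr": 0.001, "BaA": 0.1, "BbF": 0.1,
    "BkF": 0.1, "BaP": 1.0, "InP": 0.1, "DBA": 1.0, "BghiP": 0.01,
}

TEF_SETS: dict[str, dict[str, float]] = {  # "study": as tabulated by the source survey
    "study": TEF_STUDY,
    "nisbet-lagoy": TEF_NISBET_LAGOY,
}

#: Negligible-concentration benchmarks (µg/kg).  The maximum-permissible
#: concentration is 100×NC for every tabulated compound.
NC_BENCHMARKS: dict[str, float] = {
    "Nap": 1.4, "Acy": 1.2, "Ace": 1.2, "Flu": 1.2, "Phe": 5.1,
    "Ant": 1.2, "Flt": 26.0, "Pyr": 1.2, "BaA": 2.5, "BbF": 2.5,
    "BkF": 24.0, "InP": 59.0, "DBA": 2.6,
}

MPC_BENCHMARKS: dict[str, float] = {k: 100.0 * v for k, v in NC_BENCHMARKS.items()}

#: Effects-range-low / effects-range-median sediment screening values (µg/kg)
#: for the compounds the survey screens.
ERL_ERM: dict[str, tuple[float, float]] = {
    "Nap": (160.0, 2100.0),
    "Acy": (44.0, 640.0),
    "Ace": (16.0, 500.0),
    "Flu": (19.0, 540.0),
    "Phe": (240.0, 1500.0),
    "Ant": (85.3, 1100.0),
    "Flt": (600.0, 5100.0),
    "Pyr": (665.0, 2600.0),
    "BaA": (261.0, 1600.0),
    "BaP": (430.0, 1600.0),
    "DBA": (63.4, 260.0),
}

#: Survey mean / maximum PAH concentrations (µg/kg).  BaP and BghiP were below
#: detection.  BkF and InP means are not tabulated by the survey and are
#: back-computed from the published risk quotients (62.4 = 2.6×24,
#: 17.7 = 0.3×59); BbF comes from the survey text (its tabulated quotient
#: implies 356.5, an internal inconsistency kept out of the calibration).
SURVEY_PAH_MEANS: dict[str, float] = {
    "Nap": 4.46, "Acy": 9.2, "Ace": 2.25, "Flu": 27.53, "Phe": 100.85,
    "Ant": 141.02, "Flt": 21.89, "Pyr": 12.61, "BaA": 60.7, "BbF": 51.356,
    "BkF": 62.4, "InP": 17.7, "DBA": 31.65,
}

SURVEY_PAH_MAXIMA: dict[str, float] = {
    "Nap": 12.13, "Acy": 33.38, "Ace": 12.1, "Flu": 67.37, "Phe": 234.31,
    "Ant": 476.35, "Flt": 85.29, "Pyr": 96.47, "BaA": 162.16, "DBA": 35.34,
}

#: Compounds reported below the detection limit across the survey.
SURVEY_ND_COMPOUNDS = ("BaP", "BghiP")

# --------------------------------------------------------------------------
# Exposure profiles
# --------------------------------------------------------------------------

#: Soil-exposure profile for PTE hazard assessment.  IngR in mg soil/day,
#: InhR m³/day, EF day/yr, ED yr, SA cm², AF mg/cm² per event (one event/day),
#: ABF dimensionless dermal absorption, BW kg, CF kg/mg, PEF m³/kg, AT days.
PTE_EXPOSURE_PROFILES: dict[str, dict[str, float]] = {
    "child": {
        "IngR": 200.0, "InhR": 7.6, "EF": 350.0, "ED": 6.0,
        "SA": 2800.0, "AF": 0.2, "ABF": 0.001, "BW": 15.0,
        "CF": 1e-6, "PEF": 1.36e9, "AT_nc": 365.0 * 6, "AT_ca": 25550.0,
    },
    "adult": {
        "IngR": 100.0, "InhR": 20.0, "EF": 350.0, "ED": 30.0,
        "SA": 3300.0, "AF": 0.7, "ABF": 0.001, "BW": 70.0,
        "CF": 1e-6, "PEF": 1.36e9, "AT_nc": 365.0 * 30, "AT_ca": 25550.0,
    },
}

#: Lifetime-cancer-risk profile for PAH exposure (a distinct parameter set:
#: shorter exposure frequency, adult BW 61.5 kg, adult SA 5700 cm²).
#: IR_ing mg/day, IR_inh m³/day, AT = 70 y lifetime for both receptors.
ILCR_EXPOSURE_PROFILES: dict[str, dict[str, float]] = {
    "child": {
        "BW": 15.0, "EF": 180.0, "ED": 6.0, "IR_inh": 10.0, "IR_ing": 200.0,
        "SA": 2800.0, "AF": 0.2, "ABS": 0.13, "AT": 365.0 * 70, "PEF": 1.36e9,
    },
    "adult": {
        "BW": 61.5, "EF": 180.0, "ED": 24.0, "IR_inh": 20.0, "IR_ing": 100.0,
        "SA": 5700.0, "AF": 0.07, "ABS": 0.13, "AT": 365.0 * 70, "PEF": 1.36e9,
    },
}

#: Pathway-specific cancer slope factors for benzo[a]pyrene equivalents,
#: (mg/(kg·day))⁻¹.
CSF: dict[str, float] = {"ingestion": 3.7, "dermal": 25.0, "inhalation": 85.3}

# --------------------------------------------------------------------------
# Pb isotope end-members
# --------------------------------------------------------------------------

#: ²⁰⁶Pb/²⁰⁷Pb signatures and Pb concentrations (mg/kg) of the three source
#: end-members: geogenic bedrock, industrial emissions, vehicle traffic.
#: The industrial ratio is reported as a range; the default is its midpoint.
#: The industrial/traffic concentration is reported both as 2397 and 2379;
#: 2397 (first occurrence) is the default, with the traffic concentration
#: duplicating the industrial one as reported.
PB_END_MEMBERS: dict[str, dict[str, float]] = {
    "geogenic":   {"r206_207": 1.2252, "c_pb": 6681.0},
    "industrial": {"r206_207": 1.1497, "c_pb": 2397.0},
    "traffic":    {"r206_207": 1.097,  "c_pb": 2397.0},
}

R2_INDUSTRIAL_RANGE = (1.1427, 1.1567)
C2_ALTERNATE = 2379.0

#: Synthetic ²⁰⁸Pb/²⁰⁷Pb end-member signatures (the study defines the soil
#: ratio but prints no source values); used by the overdetermined solver and
#: the forward generator only.
PB_END_MEMBERS_R208: dict[str, float] = {
    "geogenic": 2.476, "industrial": 2.41, "traffic": 2.38,
}

#: Published per-sample source fractions (geogenic, industrial, traffic) for
#: the twelve isotopically characterised samples.
SOURCE_FRACTION_TABLE: dict[str, tuple[float, float, float]] = {
    "S1": (0.30, 0.50, 0.20), "S2": (0.25, 0.50, 0.25),
    "S3": (0.10, 0.60, 0.30), "S4": (0.35, 0.45, 0.20),
    "S5": (0.20, 0.60, 0.20), "S6": (0.40, 0.40, 0.20),
    "S7": (0.45, 0.40, 0.15), "S8": (0.15, 0.55, 0.30),
    "S9": (0.35, 0.45, 0.20), "S10": (0.10, 0.70, 0.20),
    "S11": (0.25, 0.50, 0.25), "S12": (0.20, 0.50, 0.30),
}

# --------------------------------------------------------------------------
# Combined Isotopic Impact Index (CISI)
# --------------------------------------------------------------------------

#: Default chemical parameters entering the chemical index, reference
#: isotopic ratios, and aggregation weights.
CISI_DEFAULTS = {
    "chemical_parameters": ("pH", "Fe", "Mn", "Pb", "Ca"),
    "r206_207_ref": 1.2,
    "r208_207_ref": 2.5,
    "w_chemical": 0.6,
    "w_isotopic": 0.4,
}
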