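"""Shared clinical parameter vocabulary.

LOINC codes are used for the laboratory and vital-sign parameters that
have unambiguous LOINC representations; the computed 10-year
cardiovascular risk lives in a local code system because no national lab
code system is in scope.
"""

from dmpkit.model import LOCAL, LOINC, CodedConcept

SBP = CodedConcept(system=LOINC, code="8480-6", display="Systolic blood pressure")
DBP = CodedConcept(system=LOINC, code="8462-4", display="Diastolic blood pressure")
FPG = CodedConcept(system=LOINC, code="1558-6", display="Fasting plasma glucose")
HBA1C = CodedConcept(system=LOINC, code="4548-4", display="Hemoglobin A1c")
LDL = CodedConcept(system=LOINC, code="18262-6", display="LDL cholesterol")
HDL = CodedConcept(system=LOINC, code="2085-9", display="HDL cholesterol")
TRIGLYCERIDE = CodedConcept(system=LOINC, code="2571-8", display="Triglyceride")
TOTAL_CHOLESTEROL = CodedConcept(system=LOINC, code="2093-3",
                                 display="Total cholesterol")
WEIGHT = CodedConcept(system=LOINC, code="29463-7", display="Body weight")
HEIGHT = CodedConcept(system=LOINC, code="8302-2", display="Body height")
BMI = CodedConcept(system=LOINC, code="39156-5", display="Body mass index")
WAIST = CodedConcept(system=LOINC, code="8280-0", display="Waist circumference")
EGFR = CodedConcept(system=LOINC, code="62238-1",
                    display="Estimated glomerular filtration rate")
CVD_RISK = CodedConcept(system=LOCAL, code="cvd-10yr-risk",
                        display="10-year fatal cardiovascular risk")
SMOKER = CodedConcept(system=LOCAL, code="current-smoker",
                      display="Current smoker (1=yes, 0=no)")

DEFAULT_UNITS = {
    SBP.key(): "mmHg",
    DBP.key(): "mmHg",
    FPG.key(): "mg/dL",
    HBA1C.key(): "%",
    LDL.key(): "mg/dL",
    HDL.key(): "mg/dL",
    TRIGLYCERIDE.key(): "mg/dL",
    TOTAL_CHOLESTEROL.key(): "mmol/L",
    WEIGHT.key(): "kg",
    HEIGHT.key(): "cm",
    BMI.key(): "kg/m2",
    WAIST.key(): "cm",
    EGFR.key(): "mL/min/1.73m2",
    CVD_RISK.key(): "%",
    SMOKER.key(): "",
}

ALL_PARAMETERS = [SBP, DBP, FPG, HBA1C, LDL, HDL, TRIGLYCERIDE,
                  TOTAL_CHOLESTEROL, WEIGHT, HEIGHT, BMI, WAIST, EGFR,
                  CVD_RISK, SMOKER]

_BY_CODE = {c.code: c for c in ALL_PARAMETERS}


def by_code(code: str) -> CodedConcept:
    """Resolve a bare parameter code to its full concept."""
    if code not in _BY_CODE:
        raise KeyError(f"unknown parameter code {code!r}")
    return _BY_CODE[code]


# Unit conversion factors between conventional (mg/dL) and SI (mmol/L).
GLUCOSE_MGDL_PER_MMOLL = 18.018
CHOLESTEROL_MGDL_PER_MMOLL = 38.67


def glucose_mgdl_to_mmoll(value: float) -> float:
    return value / GLUCOSE_MGDL_PER_MMOLL


def glucose_mmoll_to_mgdl(value: float) -> float:
    return value * GLUCOSE_MGDL_PER_MMOLL


def cholesterol_mgdl_to_mmoll(value: float) -> float:
    return value / CHOLESTEROL_MGDL_PER_MMOLL


def cholesterol_mmoll_to_mgdl(value: float) -> float:
    return value * CHOLESTEROL_MGDL_PER_MMOLL
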