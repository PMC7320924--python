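"""Shared categorical schema: age bands, sexes, tumour stages, quintiles.

The analysis is restricted to adults aged 30+, stratified into thirteen
5-year bands (the last band is open-ended). Stages III and IV are pooled
because distant-metastatic melanoma is rare at small-area resolution.
"""

from __future__ import annotations

AGE_GROUPS: tuple[str, ...] = (
    "30-34", "35-39", "40-44", "45-49", "50-54", "55-59", "60-64",
    "65-69", "70-74", "75-79", "80-84", "85-89", "90+",
)

SEXES: tuple[str, ...] = ("F", "M")

STAGES: tuple[str, ...] = ("I", "II", "III-IV")

QUINTILES: tuple[str, ...] = ("Q1", "Q2", "Q3", "Q4", "Q5")

#: Default adult (30+) age composition used by the population generator.
#: Loosely modelled on a western-European national pyramid; configurable.
DEFAULT_AGE_PYRAMID: dict[str, float] = {
    "30-34": 0.105, "35-39": 0.100, "40-44": 0.100, "45-49": 0.100,
    "50-54": 0.095, "55-59": 0.085, "60-64": 0.080, "65-69": 0.080,
    "70-74": 0.075, "75-79": 0.060, "80-84": 0.050, "85-89": 0.040,
    "90+": 0.030,
}

CASE_COLUMNS = ("case_id", "area_id", "sex", "age_group", "year", "stage")
POP_COLUMNS = ("area_id", "sex", "age_group", "year", "person_years")


def validate_stage(stage: str) -> str:
    if stage not in STAGES:
        raise ValueError(f"unknown stage label {stage!r}; expected one of {STAGES}")
    return stage
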