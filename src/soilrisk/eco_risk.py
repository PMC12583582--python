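"""Hakanson potential ecological risk: single-element factor Er and index RI.

Er = Tr · C / Cn, where Tr is the element's toxic-response factor and Cn a
background (upper-continental-crust) reference concentration; RI is the sum
of Er over the assessed elements.  Grading uses the standard Hakanson bands
with lower-inclusive boundaries (a value exactly on a threshold takes the
higher class).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .core_data import ParameterRegistry, SoilSample


class ErGrade(enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    CONSIDERABLE = "considerable"
    HIGH = "high"
    VERY_HIGH = "very_high"


class RiGrade(enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    CONSIDERABLE = "considerable"
    HIGH = "high"


#: Lower-inclusive class boundaries.
_ER_BANDS = ((40.0, ErGrade.LOW), (80.0, ErGrade.MODERATE),
             (160.0, ErGrade.CONSIDERABLE), (320.0, ErGrade.HIGH))
_RI_BANDS = ((150.0, RiGrade.LOW), (300.0, RiGrade.MODERATE),
             (600.0, RiGrade.CONSIDERABLE))


@dataclass
class EcoRiskResult:
    sample_id: str
    er: dict[str, float]
    er_grade: dict[str, ErGrade]
    ri: float
    ri_grade: RiGrade


def compute_Er(c: float, tr: float, cn: float) -> float:
    """Single-element potential ecological risk factor Tr·C/Cn."""
    if cn <= 0:
        raise ValueError(f"reference concentration must be positive, got {cn}")
    if tr <= 0:
        raise ValueError(f"toxic-response factor must be positive, got {tr}")
    if c < 0:
        raise ValueError(f"concentration must be non-negative, got {c}")
    return tr * c / cn


def compute_RI(er_values: dict[str, float]) -> float:
    """Risk index: exact sum of the single-element factors."""
    if not er_values:
        raise ValueError("need at least one element")
    return float(sum(er_values.values()))


def grade_Er(er: float) -> ErGrade:
    if er < 0:
        raise ValueError(f"Er must be non-negative, got {er}")
    for upper, grade in _ER_BANDS:
        if er < upper:
            return grade
    return ErGrade.VERY_HIGH


def grade_RI(ri: float) -> RiGrade:
    if ri < 0:
        raise ValueError(f"RI must be non-negative, got {ri}")
    for upper, grade in _RI_BANDS:
        if ri < upper:
            return grade
    return RiGrade.HIGH


def assess_sample(sample: SoilSample,
                  registry: ParameterRegistry | None = None,
                  elements=None) -> EcoRiskResult:
    """Er per element (those present in the sample) and the aggregate RI."""
    registry = registry or ParameterRegistry()
    elements = [el for el in (elements or sample.pte) if el in sample.pte]
    if not elements:
        raise ValueError(f"sample {sample.sample_id}: no assessable elements")
    er = {el: compute_Er(sample.pte[el], registry.tr_for(el), registry.ucc_for(el))
          for el in elements}
    ri = compute_RI(er)
    return EcoRiskResult(
        sample_id=sample.sample_id,
        er=er,
        er_grade={el: grade_Er(v) for el, v in er.items()},
        ri=ri,
        ri_grade=grade_RI(ri),
    )


def assess_survey(samples, registry: ParameterRegistry | None = None,
                  elements=None) -> list[EcoRiskResult]:
    registry = registry or ParameterRegistry()
    return [assess_sample(s, registry, elements) for s in samples]
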