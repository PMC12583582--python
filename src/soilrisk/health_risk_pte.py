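"""USEPA-style human health risk for potentially toxic elements.

Average daily doses (ADD, mg contaminant per kg body weight per day) are
computed for three exposure pathways — incidental soil ingestion, inhalation
of resuspended particles, and dermal contact — for adult and child receptors:

    ADD_ing  = C·IngR·CF·EF·ED / (BW·AT)
    ADD_inh  = C·InhR·EF·ED / (PEF·BW·AT)
    ADD_derm = C·SA·CF·AF·ABF·EF·ED / (BW·AT)

Hazard quotients divide each dose by the pathway reference dose, the hazard
index sums them, and carcinogenic risk multiplies the summed doses by the
element's slope factor.

The published inhalation formula carries an ingestion rate and a mass
conversion factor that double-count the m³→kg conversion already performed by
the particle emission factor; the default implementation is the dimensionally
consistent form above, while ``strict_published_formulas=True`` reproduces the
printed expression verbatim for comparison.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .core_data import ParameterRegistry, SoilSample

PATHWAYS = ("ingestion", "inhalation", "dermal")


class RiskBand(enum.Enum):
    NEGLIGIBLE = "negligible"          # CR < 1e-6
    ACCEPTABLE_RANGE = "acceptable"    # 1e-6 ≤ CR ≤ 1e-4
    UNACCEPTABLE = "unacceptable"      # CR > 1e-4


@dataclass
class ExposureDose:
    receptor: str
    pathway: str
    add: float  # mg/(kg·day)


@dataclass
class HealthRiskResult:
    sample_id: str
    element: str
    receptor: str
    hq: dict[str, float]
    hi: float
    cr: float | None
    cr_band: RiskBand | None
    hi_exceeds_one: bool = field(init=False)

    def __post_init__(self) -> None:
        self.hi_exceeds_one = self.hi > 1.0


def compute_ADD(c: float, pathway: str, profile: dict[str, float],
                receptor: str = "receptor", carcinogenic: bool = False,
                strict_published_formulas: bool = False) -> ExposureDose:
    """Average daily dose for one pathway under an exposure profile.

    ``carcinogenic`` selects the lifetime averaging time AT_ca instead of the
    exposure-duration-linked AT_nc.
    """
    if c < 0:
        raise ValueError(f"concentration must be non-negative, got {c}")
    at = profile["AT_ca"] if carcinogenic else profile["AT_nc"]
    if at <= 0 or profile["BW"] <= 0:
        raise ValueError("AT and BW must be positive")
    common = profile["EF"] * profile["ED"] / (profile["BW"] * at)
    if pathway == "ingestion":
        add = c * profile["IngR"] * profile["CF"] * common
    elif pathway == "inhalation":
        if strict_published_formulas:
            # Verbatim published form: ingestion rate and CF inside the
            # inhalation dose.
            add = c * profile["IngR"] * profile["CF"] * common / profile["PEF"]
        else:
            add = c * profile["InhR"] * common / profile["PEF"]
    elif pathway == "dermal":
        add = (c * profile["SA"] * profile["CF"] * profile["AF"]
               * profile["ABF"] * common)
    else:
        raise ValueError(f"unknown pathway {pathway!r}")
    return ExposureDose(receptor=receptor, pathway=pathway, add=add)


def compute_HQ(add: ExposureDose, rfd: float) -> float:
    """Hazard quotient ADD/RfD."""
    if rfd <= 0:
        raise ValueError(f"reference dose must be positive, got {rfd}")
    return add.add / rfd


def compute_HI(hqs) -> float:
    """Hazard index: exact sum of the pathway hazard quotients."""
    hqs = dict(hqs) if isinstance(hqs, dict) else {i: v for i, v in enumerate(hqs)}
    if not hqs:
        raise ValueError("need at least one hazard quotient")
    return float(sum(hqs.values()))


def compute_CR(adds: dict[str, ExposureDose], sf: float) -> float:
    """Carcinogenic risk: (ADD_ing + ADD_inh + ADD_derm) · SF."""
    if sf <= 0:
        raise ValueError(f"slope factor must be positive, got {sf}")
    missing = [p for p in PATHWAYS if p not in adds]
    if missing:
        raise ValueError(f"missing pathway dose(s): {missing}")
    return sum(adds[p].add for p in PATHWAYS) * sf


def band_CR(cr: float) -> RiskBand:
    if cr < 1e-6:
        return RiskBand.NEGLIGIBLE
    if cr <= 1e-4:
        return RiskBand.ACCEPTABLE_RANGE
    return RiskBand.UNACCEPTABLE


def assess_element(c: float, element: str, receptor: str,
                   registry: ParameterRegistry | None = None,
                   sample_id: str = "",
                   strict_published_formulas: bool = False) -> HealthRiskResult:
    """HQ per pathway, HI and (where a slope factor exists) CR for one
    element concentration and receptor."""
    registry = registry or ParameterRegistry()
    if receptor not in registry.pte_profiles:
        raise ValueError(f"unknown receptor {receptor!r}")
    profile = registry.pte_profiles[receptor]

    hq = {}
    for pathway in PATHWAYS:
        dose = compute_ADD(c, pathway, profile, receptor,
                           carcinogenic=False,
                           strict_published_formulas=strict_published_formulas)
        hq[pathway] = compute_HQ(dose, registry.rfd_for(element, pathway))
    hi = compute_HI(hq)

    cr = cr_band = None
    if element in registry.sf:
        adds_ca = {p: compute_ADD(c, p, profile, receptor, carcinogenic=True,
                                  strict_published_formulas=strict_published_formulas)
                   for p in PATHWAYS}
        cr = compute_CR(adds_ca, registry.sf_for(element))
        cr_band = band_CR(cr)

    return HealthRiskResult(sample_id=sample_id, element=element,
                            receptor=receptor, hq=hq, hi=hi,
                            cr=cr, cr_band=cr_band)


def assess_sample(sample: SoilSample, registry: ParameterRegistry | None = None,
                  receptors=("adult", "child"),
                  strict_published_formulas: bool = False) -> list[HealthRiskResult]:
    registry = registry or ParameterRegistry()
    return [assess_element(c, el, receptor, registry, sample.sample_id,
                           strict_published_formulas)
            for el, c in sample.pte.items()
            for receptor in receptors]
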