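"""PAH toxicity: BaP equivalents, TEQ, ERL/ERM screening, composition,
and incremental lifetime cancer risk (ILCR).

Each compound's concentration is weighted by its toxicity equivalency factor
(TEF, potency relative to benzo[a]pyrene) to a BaP-equivalent; their sum is
the toxic equivalent concentration TEQ (µg/kg).  ILCR converts the TEQ into
a lifetime cancer probability per exposure pathway:

    ILCR_ing  = cs·(CSF_ing·∛(BW/70))·IR_ing·EF·ED / (BW·AT·10⁶)
    ILCR_derm = cs·(CSF_derm·∛(BW/70))·SA·AF·ABS·EF·ED / (BW·AT·10⁶)
    ILCR_inh  = cs·(CSF_inh·∛(BW/70))·IR_inh·EF·ED / (BW·AT·PEF)

The 10⁶ divisor is the µg/kg→kg conversion for the mass-based pathways;
inhalation uses the particle emission factor instead.  The body-weight cube
root rescales the BaP slope factors from the 70 kg reference body.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .core_data import PAHProfile, ParameterRegistry
from . import constants


class ScreeningClass(enum.Enum):
    MINIMAL = "minimal"            # below ERL
    POSSIBLE = "possible"          # [ERL, ERM)
    PROBABLE = "probable"          # >= ERM
    NOT_DETECTED = "not_detected"


@dataclass
class TeqResult:
    sample_id: str
    bapeq: dict[str, float]
    teq: float
    teq_fraction: float  # TEQ / ΣPAH over the same compounds


@dataclass
class IlcrResult:
    receptor: str
    ilcr: dict[str, float]   # per pathway
    total: float             # cancer risk, sum of the three pathways


def compute_teq(profile: PAHProfile, tefs: dict[str, float] | None = None,
                registry: ParameterRegistry | None = None,
                tef_set: str = "study", nd_policy: str = "exclude",
                lod: dict[str, float] | None = None) -> TeqResult:
    """BaP-equivalents and their sum.  ND compounds are excluded by default
    (the survey's below-detection compounds contribute nothing)."""
    registry = registry or ParameterRegistry()
    conc = profile.concentrations(nd_policy, lod)
    if tefs is None:
        tefs = {c: registry.tef_for(c, tef_set) for c in conc}
    missing = sorted(set(conc) - set(tefs))
    if missing:
        raise KeyError(f"no TEF for compound(s): {missing}")
    bapeq = {c: conc[c] * tefs[c] for c in conc}
    teq = float(sum(bapeq.values()))
    total = float(sum(conc.values()))
    return TeqResult(profile.sample_id, bapeq, teq,
                     teq / total if total > 0 else 0.0)


def compute_ilcr(cs: float, receptor: str,
                 registry: ParameterRegistry | None = None,
                 profile: dict[str, float] | None = None,
                 csf: dict[str, float] | None = None) -> IlcrResult:
    """Incremental lifetime cancer risk from a TEQ of ``cs`` µg/kg."""
    registry = registry or ParameterRegistry()
    if profile is None:
        if receptor not in registry.ilcr_profiles:
            raise ValueError(f"receptor must be one of "
                             f"{sorted(registry.ilcr_profiles)}, got {receptor!r}")
        profile = registry.ilcr_profiles[receptor]
    csf = csf or registry.csf
    if cs < 0:
        raise ValueError(f"TEQ must be non-negative, got {cs}")
    bw, at = profile["BW"], profile["AT"]
    if bw <= 0 or at <= 0:
        raise ValueError("BW and AT must be positive")
    scale = (bw / 70.0) ** (1.0 / 3.0)
    ef_ed = profile["EF"] * profile["ED"]
    ilcr = {
        "ingestion": cs * (csf["ingestion"] * scale) * profile["IR_ing"]
        * ef_ed / (bw * at * 1e6),
        "dermal": cs * (csf["dermal"] * scale) * profile["SA"] * profile["AF"]
        * profile["ABS"] * ef_ed / (bw * at * 1e6),
        "inhalation": cs * (csf["inhalation"] * scale) * profile["IR_inh"]
        * ef_ed / (bw * at * profile["PEF"]),
    }
    return IlcrResult(receptor, ilcr, float(sum(ilcr.values())))


def screen_erl_erm(profile: PAHProfile,
                   registry: ParameterRegistry | None = None
                   ) -> dict[str, ScreeningClass]:
    """Three-way effects-range screening per compound; ND compounds are
    reported as such, compounds without benchmarks are skipped."""
    registry = registry or ParameterRegistry()
    out = {}
    for cmp_, c in profile.pah.items():
        if cmp_ not in registry.erl_erm:
            continue
        if c is None:
            out[cmp_] = ScreeningClass.NOT_DETECTED
            continue
        erl, erm = registry.erl_erm_for(cmp_)
        if c < erl:
            out[cmp_] = ScreeningClass.MINIMAL
        elif c < erm:
            out[cmp_] = ScreeningClass.POSSIBLE
        else:
            out[cmp_] = ScreeningClass.PROBABLE
    return out


def composition_summary(profile: PAHProfile) -> dict[str, float]:
    """Mass fractions of low-molecular-weight (2–3 ring), high-molecular-weight
    (4–6 ring) and carcinogen-classified compounds among detected mass."""
    conc = profile.detected()
    total = sum(conc.values())
    if not conc or total <= 0:
        raise ValueError(f"sample {profile.sample_id}: no detected PAH mass")
    lmw = sum(c for k, c in conc.items()
              if constants.PAH_COMPOUNDS[k]["rings"] <= 3)
    carc = sum(c for k, c in conc.items()
               if constants.PAH_COMPOUNDS[k]["carcinogenic"])
    return {"lmw_fraction": lmw / total,
            "hmw_fraction": (total - lmw) / total,
            "carcinogenic_fraction": carc / total,
            "total": total}
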