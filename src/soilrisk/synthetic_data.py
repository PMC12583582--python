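"""Seeded synthetic survey generator.

Emulates the statistical structure of the 53-sample urban-soil survey so that
every pipeline stage is testable without external data:

* element concentrations: truncated lognormal per element, calibrated to the
  survey's per-element mean and coefficient of variation and truncated to the
  survey's observed range.  The lognormal location is root-found so that the
  *truncated* mean matches the target exactly; the spread is set from the
  untruncated cv (truncation shrinks it somewhat, which the survey's own
  bounded ranges also imply).  The strong right skew of the published shape
  statistics motivates the lognormal family.
* PAH concentrations: lognormal per compound with the mean matched exactly
  and the spread calibrated so the survey's observed maximum sits near the
  (1 − 1/53) quantile; the survey's two below-detection compounds are
  injected as ND.
* isotope measurements: source fractions drawn from a Dirichlet and pushed
  through the forward mixing model, with optional multiplicative noise; the
  ground-truth fractions are returned for recovery testing.

Elements are drawn independently: the survey reports no inter-element
correlations to emulate.  A single top-level seed deterministically derives
the per-stream substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

from . import constants
from .core_data import IsotopeMeasurement, LandUse, PAHProfile, SoilSample
from .pb_mixing import EndMemberSet, default_r_prime, forward_mix

#: number of samples in the emulated survey; fixes the quantile used to
#: calibrate the PAH spread regardless of how many samples are generated
_STUDY_N = 53

#: synthetic ²⁰⁷Pb/²⁰⁴Pb anchor used to expand the 207-normalised ratios into
#: a full, internally consistent ratio set
_R207_204 = 15.64


@dataclass
class GeneratorSpec:
    """Calibration targets and knobs for the generator.

    Defaults are the published survey conditions; override per-field for
    what-if experiments.
    """

    n_samples: int = _STUDY_N
    seed: int = 0
    #: element → (min, max, mean, sd); defaults from the survey summary table
    pte_targets: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            el: constants.SURVEY_PTE_STATS[el][:4] for el in constants.ELEMENTS})
    ph_range: tuple[float, float] = (
        constants.SURVEY_PTE_STATS["pH"][0], constants.SURVEY_PTE_STATS["pH"][1])
    ec_target: tuple[float, float, float, float] = (
        constants.SURVEY_PTE_STATS["EC"][:4])
    pah_means: dict[str, float] = field(
        default_factory=lambda: dict(constants.SURVEY_PAH_MEANS))
    pah_maxima: dict[str, float] = field(
        default_factory=lambda: dict(constants.SURVEY_PAH_MAXIMA))
    nd_compounds: tuple[str, ...] = constants.SURVEY_ND_COMPOUNDS
    end_members: EndMemberSet = field(default_factory=EndMemberSet)
    #: Dirichlet concentration for (geogenic, industrial, traffic); means
    #: ≈ (0.26, 0.51, 0.23) as in the published per-sample fraction table
    dirichlet_alpha: tuple[float, float, float] = (2.6, 5.1, 2.3)
    ratio_noise: float = 0.0  # multiplicative sd on generated ratios
    conc_noise: float = 0.0   # multiplicative sd on generated Pb concentration
    land_use_weights: dict[str, float] = field(default_factory=lambda: {
        "industrial": 0.25, "residential": 0.35,
        "traffic": 0.25, "green_space": 0.15})

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("Dirichlet parameters must be positive")
        for el, (lo, hi, mean, sd) in self.pte_targets.items():
            if not (0 <= lo < hi) or mean <= 0 or sd <= 0:
                raise ValueError(f"invalid targets for {el}")
            if not lo < mean < hi:
                raise ValueError(
                    f"{el}: target mean {mean} outside bounds ({lo}, {hi})")
            if sd > (hi - lo):
                raise ValueError(
                    f"{el}: target sd {sd} infeasible for bounds ({lo}, {hi})")


# --------------------------------------------------------------------------
# distribution calibration
# --------------------------------------------------------------------------

def _truncated_lognormal_mean(mu: float, sigma: float,
                              lo: float, hi: float) -> float:
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    z = scipy.stats.norm.cdf(b) - scipy.stats.norm.cdf(a)
    if z <= 0:
        return lo if mu < np.log(lo) else hi
    num = scipy.stats.norm.cdf(b - sigma) - scipy.stats.norm.cdf(a - sigma)
    return float(np.exp(mu + sigma**2 / 2) * num / z)


def _calibrate_truncated_lognormal(mean: float, sd: float,
                                   lo: float, hi: float) -> tuple[float, float]:
    """Location/scale of a lognormal whose [lo, hi]-truncation has the target
    mean; scale from the untruncated cv."""
    cv = sd / mean
    sigma = float(np.sqrt(np.log1p(cv**2)))
    lo_mu, hi_mu = np.log(lo) - 10 * sigma, np.log(hi) + 10 * sigma
    mu = scipy.optimize.brentq(
        lambda m: _truncated_lognormal_mean(m, sigma, lo, hi) - mean,
        lo_mu, hi_mu, xtol=1e-12)
    return float(mu), sigma


def _sample_truncated_lognormal(rng: np.random.Generator, n: int, mu: float,
                                sigma: float, lo: float, hi: float) -> np.ndarray:
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    u = rng.uniform(scipy.stats.norm.cdf(a), scipy.stats.norm.cdf(b), size=n)
    return np.exp(mu + sigma * scipy.stats.norm.ppf(u))


def _calibrate_pah_sigma(mean: float, observed_max: float | None) -> float:
    """Lognormal scale such that the observed survey maximum is near the
    (1 − 1/n_study) quantile; falls back to cv = 1 when no maximum is
    recorded or the ratio is too tight."""
    default_sigma = float(np.sqrt(np.log(2.0)))  # cv = 1
    if observed_max is None or observed_max <= mean:
        return default_sigma
    z = float(scipy.stats.norm.ppf(1.0 - 1.0 / _STUDY_N))
    disc = z**2 - 2.0 * np.log(observed_max / mean)
    if disc <= 0:
        return default_sigma
    return float(z - np.sqrt(disc))


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("pte", "pah", "isotope", "landuse")
    return {nm: np.random.default_rng(ss) for nm, ss in zip(names, children)}


def generate_pte_survey(spec: GeneratorSpec | None = None) -> list[SoilSample]:
    """Element concentrations + pH/EC for ``n_samples`` locations."""
    spec = spec or GeneratorSpec()
    rng = _streams(spec.seed)["pte"]
    lu_rng = _streams(spec.seed)["landuse"]
    n = spec.n_samples
    columns = {}
    for el, (lo, hi, mean, sd) in spec.pte_targets.items():
        mu, sigma = _calibrate_truncated_lognormal(mean, sd, lo, hi)
        columns[el] = _sample_truncated_lognormal(rng, n, mu, sigma, lo, hi)
    ph = rng.uniform(*spec.ph_range, size=n)
    ec_lo, ec_hi, ec_mean, ec_sd = spec.ec_target
    mu, sigma = _calibrate_truncated_lognormal(ec_mean, ec_sd, ec_lo, ec_hi)
    ec = _sample_truncated_lognormal(rng, n, mu, sigma, ec_lo, ec_hi)
    uses = list(spec.land_use_weights)
    w = np.array([spec.land_use_weights[u] for u in uses], dtype=float)
    land = lu_rng.choice(uses, size=n, p=w / w.sum())
    return [
        SoilSample(
            sample_id=f"S{i + 1}",
            pte={el: float(columns[el][i]) for el in columns},
            ph=float(ph[i]), ec=float(ec[i]), land_use=LandUse(land[i]))
        for i in range(n)
    ]


def generate_pah_survey(spec: GeneratorSpec | None = None) -> list[PAHProfile]:
    """Per-compound PAH concentrations; the survey's below-detection
    compounds are ND in every sample."""
    spec = spec or GeneratorSpec()
    rng = _streams(spec.seed)["pah"]
    n = spec.n_samples
    columns: dict[str, np.ndarray] = {}
    for cmp_, mean in spec.pah_means.items():
        sigma = _calibrate_pah_sigma(mean, spec.pah_maxima.get(cmp_))
        mu = np.log(mean) - sigma**2 / 2  # exact lognormal mean match
        columns[cmp_] = rng.lognormal(mu, sigma, size=n)
    profiles = []
    for i in range(n):
        pah: dict[str, float | None] = {c: float(columns[c][i]) for c in columns}
        for nd in spec.nd_compounds:
            pah[nd] = None
        profiles.append(PAHProfile(sample_id=f"S{i + 1}", pah=pah))
    return profiles


def generate_isotope_survey(
        spec: GeneratorSpec | None = None
) -> tuple[list[IsotopeMeasurement], np.ndarray]:
    """Isotope measurements forward-generated from Dirichlet source mixes.

    Returns ``(measurements, true_fractions)`` where the fraction rows are
    the hidden ground truth (geogenic, industrial, traffic) for each sample.
    With zero noise the mixing solver recovers them to numerical precision.
    """
    spec = spec or GeneratorSpec()
    rng = _streams(spec.seed)["isotope"]
    ems = spec.end_members
    if ems.r_prime is None:
        ems = EndMemberSet(ems.labels, ems.r, ems.c, default_r_prime())
    fractions = rng.dirichlet(spec.dirichlet_alpha, size=spec.n_samples)
    measurements = []
    for i, f in enumerate(fractions):
        obs = forward_mix(f, ems)
        r206_207, r208_207 = obs["r206_207"], obs["r208_207"]
        c_pb = obs["c_pb"]
        if spec.ratio_noise > 0:
            r206_207 *= 1.0 + rng.normal(0.0, spec.ratio_noise)
            r208_207 *= 1.0 + rng.normal(0.0, spec.ratio_noise)
        if spec.conc_noise > 0:
            c_pb *= float(np.exp(rng.normal(0.0, spec.conc_noise)))
        ratios = {
            "r206_207": r206_207,
            "r208_207": r208_207,
            "r207_204": _R207_204,
            "r206_204": r206_207 * _R207_204,
            "r208_204": r208_207 * _R207_204,
            "r208_206": r208_207 / r206_207,
        }
        measurements.append(IsotopeMeasurement(
            sample_id=f"S{i + 1}", ratios=ratios, pb_conc=c_pb))
    return measurements, fractions


def generate_survey(spec: GeneratorSpec | None = None):
    """All three layers at once (element, PAH, isotope), sharing the seed."""
    spec = spec or GeneratorSpec()
    soil = generate_pte_survey(spec)
    pah = generate_pah_survey(spec)
    iso, fractions = generate_isotope_survey(spec)
    return soil, pah, iso, fractions
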