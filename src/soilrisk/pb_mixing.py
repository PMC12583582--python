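"""Three-end-member Pb-isotope mixing model.

A soil sample's ²⁰⁶Pb/²⁰⁷Pb ratio and Pb concentration are represented as a
convex combination of three source signatures — geogenic bedrock (F1),
industrial emissions (F2) and vehicle traffic (F3):

    F1 + F2 + F3 = 1
    F1·R1 + F2·R2 + F3·R3 = R_soil
    F1/C1 + F2/C2 + F3/C3 = 1/C_soil

The concentration constraint is harmonic in the source concentrations: it
mixes inverse concentrations, the form under which equal soil-mass
contributions combine.  The conventional linear mass balance ΣFi·Ci = C_soil
is available behind ``concentration_rule="linear"`` for comparison, never as
the default.

The 3×3 system is solved exactly; infeasible solutions (fractions outside
[0,1], i.e. observations outside the mixing envelope) are reported with
diagnostics, never silently clipped.  An overdetermined variant adds the
²⁰⁸Pb/²⁰⁷Pb balance and solves a sum-constrained least-squares problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from . import constants


class SingularMixingError(ValueError):
    """End-member signatures are degenerate; the system cannot be inverted."""


@dataclass
class EndMemberSet:
    """Three source signatures: ²⁰⁶Pb/²⁰⁷Pb ratio, Pb concentration (mg/kg),
    optional ²⁰⁸Pb/²⁰⁷Pb ratio per source."""

    labels: tuple[str, str, str] = ("geogenic", "industrial", "traffic")
    r: tuple[float, float, float] = (
        constants.PB_END_MEMBERS["geogenic"]["r206_207"],
        constants.PB_END_MEMBERS["industrial"]["r206_207"],
        constants.PB_END_MEMBERS["traffic"]["r206_207"],
    )
    c: tuple[float, float, float] = (
        constants.PB_END_MEMBERS["geogenic"]["c_pb"],
        constants.PB_END_MEMBERS["industrial"]["c_pb"],
        constants.PB_END_MEMBERS["traffic"]["c_pb"],
    )
    r_prime: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.r) != 3 or len(self.c) != 3:
            raise ValueError("exactly three end-members required")
        if any(x <= 0 for x in self.r) or any(x <= 0 for x in self.c):
            raise ValueError("end-member ratios and concentrations must be positive")
        if len(set(self.r)) != 3:
            dupes = [lb for lb, r in zip(self.labels, self.r)
                     if list(self.r).count(r) > 1]
            raise SingularMixingError(
                f"end-members {dupes} share the same isotope ratio; "
                "the mixing system is singular")

    @classmethod
    def with_r2(cls, r2: float, c2: float | None = None) -> "EndMemberSet":
        """Variant with an explicit industrial ratio (the published value is
        a range) and optionally the alternate industrial concentration."""
        base = cls()
        c = list(base.c)
        if c2 is not None:
            c[1] = c2
            c[2] = c2
        return cls(base.labels, (base.r[0], r2, base.r[2]), tuple(c),
                   base.r_prime)


def default_r_prime() -> tuple[float, float, float]:
    em = constants.PB_END_MEMBERS_R208
    return (em["geogenic"], em["industrial"], em["traffic"])


@dataclass
class MixingResult:
    sample_id: str
    fractions: tuple[float, float, float]
    residual_norm: float
    feasible: bool
    diagnostics: str = ""
    condition_number: float = field(default=float("nan"))

    @property
    def f1(self) -> float:
        return self.fractions[0]

    @property
    def f2(self) -> float:
        return self.fractions[1]

    @property
    def f3(self) -> float:
        return self.fractions[2]


def forward_mix(f, ems: EndMemberSet | None = None,
                concentration_rule: str = "harmonic") -> dict[str, float]:
    """Predicted soil ratio(s) and Pb concentration for a fraction triple."""
    ems = ems or EndMemberSet()
    f = np.asarray(f, dtype=float)
    if f.shape != (3,):
        raise ValueError("need exactly three fractions")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {f.sum()!r}")
    if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
        raise ValueError("fractions must lie in [0, 1]")
    r = np.asarray(ems.r)
    c = np.asarray(ems.c)
    out = {"r206_207": float(f @ r)}
    if concentration_rule == "harmonic":
        out["c_pb"] = float(1.0 / (f @ (1.0 / c)))
    elif concentration_rule == "linear":
        out["c_pb"] = float(f @ c)
    else:
        raise ValueError(f"unknown concentration rule {concentration_rule!r}")
    if ems.r_prime is not None:
        out["r208_207"] = float(f @ np.asarray(ems.r_prime))
    return out


def _feasibility(f: np.ndarray, tol: float) -> tuple[bool, str]:
    if np.all(f >= -tol) and np.all(f <= 1 + tol):
        return True, ""
    bad = ", ".join(f"F{i + 1}={v:.4f}" for i, v in enumerate(f)
                    if v < -tol or v > 1 + tol)
    return False, (f"solution outside the mixing envelope ({bad}); the "
                   "observation cannot be expressed as a convex combination "
                   "of these end-members")


def solve_mix(obs: dict[str, float], ems: EndMemberSet | None = None,
              sample_id: str = "", concentration_rule: str = "harmonic",
              feasibility_tol: float = 1e-9,
              project_to_simplex: bool = False) -> MixingResult:
    """Exact solution of the three-equation mixing system.

    ``obs`` needs ``r206_207`` and ``c_pb``.  The returned fractions always
    sum to 1; ``feasible`` reports whether they also lie in [0,1].  Optional
    simplex projection is opt-in and recorded in the diagnostics.
    """
    ems = ems or EndMemberSet()
    r_soil = obs["r206_207"]
    c_soil = obs["c_pb"]
    if c_soil <= 0:
        raise ValueError(f"soil Pb concentration must be positive, got {c_soil}")
    c = np.asarray(ems.c, dtype=float)
    if concentration_rule == "harmonic":
        conc_row, conc_rhs = 1.0 / c, 1.0 / c_soil
    elif concentration_rule == "linear":
        conc_row, conc_rhs = c, c_soil
    else:
        raise ValueError(f"unknown concentration rule {concentration_rule!r}")
    a = np.array([np.ones(3), np.asarray(ems.r, dtype=float), conc_row])
    b = np.array([1.0, r_soil, conc_rhs])
    cond = float(np.linalg.cond(a))
    try:
        f = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise SingularMixingError(
            f"mixing system is singular for end-members {ems.labels}: {exc}"
        ) from exc
    residual = float(np.linalg.norm(a @ f - b))
    feasible, diag = _feasibility(f, feasibility_tol)
    if project_to_simplex and not feasible:
        f = _project_simplex(f)
        diag += " (projected onto the simplex)"
    return MixingResult(sample_id, tuple(float(x) for x in f), residual,
                        feasible, diag, cond)


def _project_simplex(f: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {f: f >= 0, sum f = 1}."""
    u = np.sort(f)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / (np.arange(3) + 1) > 0)[0][-1]
    return np.maximum(f - css[rho] / (rho + 1.0), 0.0)


def solve_mix_overdetermined(obs: dict[str, float],
                             ems: EndMemberSet | None = None,
                             sample_id: str = "",
                             concentration_rule: str = "harmonic",
                             feasibility_tol: float = 1e-6) -> MixingResult:
    """Constrained least squares using both ²⁰⁶Pb/²⁰⁷Pb and ²⁰⁸Pb/²⁰⁷Pb.

    Minimises the residual of the ratio and concentration balances subject to
    the exact sum-to-one constraint (eliminating F3), so the returned
    fractions always sum to 1 regardless of how conflicting the ratios are.
    """
    ems = ems or EndMemberSet()
    if ems.r_prime is None:
        ems = EndMemberSet(ems.labels, ems.r, ems.c, default_r_prime())
    if "r208_207" not in obs:
        raise ValueError("overdetermined solve requires an observed r208_207")
    c_soil = obs["c_pb"]
    if c_soil <= 0:
        raise ValueError(f"soil Pb concentration must be positive, got {c_soil}")
    c = np.asarray(ems.c, dtype=float)
    if concentration_rule == "harmonic":
        conc_row, conc_rhs = 1.0 / c, 1.0 / c_soil
    else:
        conc_row, conc_rhs = c, c_soil
    rows = np.array([np.asarray(ems.r, dtype=float),
                     np.asarray(ems.r_prime, dtype=float),
                     conc_row])
    rhs = np.array([obs["r206_207"], obs["r208_207"], conc_rhs])
    # normalise row scales so ratios and concentrations weigh comparably
    scale = np.abs(rhs)
    scale[scale == 0] = 1.0
    rows_s = rows / scale[:, None]
    rhs_s = rhs / scale
    # substitute f3 = 1 - f1 - f2
    a2 = rows_s[:, :2] - rows_s[:, 2:3]
    b2 = rhs_s - rows_s[:, 2]
    res = scipy.optimize.lsq_linear(a2, b2)
    f12 = res.x
    f = np.array([f12[0], f12[1], 1.0 - f12.sum()])
    residual = float(np.linalg.norm(rows @ f - rhs))
    feasible, diag = _feasibility(f, feasibility_tol)
    return MixingResult(sample_id, tuple(float(x) for x in f), residual,
                        feasible, diag, float(np.linalg.cond(a2)))


def summarize_contributions(results) -> dict[str, dict[str, float]]:
    """Per-source mean/min/max of the fraction columns."""
    results = list(results)
    if not results:
        raise ValueError("need at least one mixing result")
    f = np.array([r.fractions for r in results])
    labels = ("geogenic", "industrial", "traffic")
    return {lb: {"mean": float(f[:, i].mean()),
                 "min": float(f[:, i].min()),
                 "max": float(f[:, i].max())}
            for i, lb in enumerate(labels)}


def sensitivity_sweep(obs: dict[str, float],
                      r2_values=None,
                      ems: EndMemberSet | None = None,
                      sample_id: str = "") -> list[tuple[float, MixingResult]]:
    """Re-solve across the published industrial-ratio range (default: 15
    evenly spaced values across 1.1427–1.1567)."""
    if r2_values is None:
        lo, hi = constants.R2_INDUSTRIAL_RANGE
        r2_values = np.linspace(lo, hi, 15)
    base = ems or EndMemberSet()
    out = []
    for r2 in r2_values:
        em = EndMemberSet(base.labels, (base.r[0], float(r2), base.r[2]),
                          base.c, base.r_prime)
        out.append((float(r2), solve_mix(obs, em, sample_id)))
    return out
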