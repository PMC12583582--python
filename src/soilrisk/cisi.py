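"""Combined Isotopic Impact Index (CISI).

CISI fuses two normalised views of a soil sample into one score in [0,1]:

* chemical indices CI — min–max scaling of each chemical parameter
  (default pH, Fe, Mn, Pb, Ca) against the range of the analysed batch or a
  fixed external reference range;
* isotopic indices II — closeness of the ²⁰⁶Pb/²⁰⁷Pb and ²⁰⁸Pb/²⁰⁷Pb ratios
  to reference values (1.2 and 2.5):  II = 1 − |R − R_ref|/R_ref.

The index is the weighted mean CISI = w1·C̄I + w2·ĪI with default weights
0.6/0.4.  The published normalisation formula is written as the reciprocal
of min–max scaling, which is unbounded as Xj approaches Xmin; since every
published index value lies in [0,1] with the maximum-valued sample scoring
exactly 1, standard min–max scaling is implemented and the printed form
treated as a typo.

II is not clamped by default: deviations beyond 100% of the reference
produce negative indices and are reported as such (``clamp_ii=True``
restricts them to [0,1]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from . import constants


@dataclass
class CisiConfig:
    chemical_parameters: tuple[str, ...] = tuple(
        constants.CISI_DEFAULTS["chemical_parameters"])
    r206_207_ref: float = constants.CISI_DEFAULTS["r206_207_ref"]
    r208_207_ref: float = constants.CISI_DEFAULTS["r208_207_ref"]
    w_chemical: float = constants.CISI_DEFAULTS["w_chemical"]
    w_isotopic: float = constants.CISI_DEFAULTS["w_isotopic"]
    clamp_ii: bool = False
    #: optional fixed {parameter: (min, max)} reference ranges; otherwise the
    #: analysed batch supplies them
    reference_ranges: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.w_chemical < 0 or self.w_isotopic < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w_chemical + self.w_isotopic - 1.0) > 1e-12:
            raise ValueError(
                f"weights must sum to 1, got "
                f"{self.w_chemical} + {self.w_isotopic}")
        if self.r206_207_ref <= 0 or self.r208_207_ref <= 0:
            raise ValueError("reference ratios must be positive")


@dataclass
class CisiResult:
    sample_id: str
    ci: dict[str, float]
    ii: dict[str, float]
    ci_mean: float
    ii_mean: float
    cisi: float
    rank: int | None = field(default=None)  # 1 = most impacted in the batch


def chemical_index(x: float, xmin: float, xmax: float) -> float:
    """Min–max scaled chemical index; out-of-range values clamp with a warning."""
    if xmax <= xmin:
        raise ValueError(f"degenerate range [{xmin}, {xmax}]")
    if x < xmin or x > xmax:
        warnings.warn(f"value {x} outside reference range [{xmin}, {xmax}]; "
                      "clamping", stacklevel=2)
        x = min(max(x, xmin), xmax)
    return (x - xmin) / (xmax - xmin)


def isotopic_index(r: float, r_ref: float, clamp: bool = False) -> float:
    """1 − relative deviation from the reference ratio; ≤ 1, possibly
    negative for deviations beyond 100% unless clamped."""
    if r_ref <= 0:
        raise ValueError(f"reference ratio must be positive, got {r_ref}")
    ii = 1.0 - abs(r - r_ref) / r_ref
    return min(max(ii, 0.0), 1.0) if clamp else ii


def compute_cisi(ci_values, ii_values,
                 config: CisiConfig | None = None,
                 sample_id: str = "") -> CisiResult:
    """Aggregate pre-computed chemical and isotopic indices into the CISI."""
    config = config or CisiConfig()
    ci = dict(ci_values) if isinstance(ci_values, dict) \
        else {f"ci_{i}": v for i, v in enumerate(ci_values)}
    ii = dict(ii_values) if isinstance(ii_values, dict) \
        else {f"ii_{i}": v for i, v in enumerate(ii_values)}
    if not ci:
        raise ValueError("need at least one chemical index")
    if not ii:
        raise ValueError("need at least one isotopic index")
    ci_mean = float(np.mean(list(ci.values())))
    ii_mean = float(np.mean(list(ii.values())))
    cisi = config.w_chemical * ci_mean + config.w_isotopic * ii_mean
    return CisiResult(sample_id, ci, ii, ci_mean, ii_mean, float(cisi))


def assess_batch(chemistry: pd.DataFrame, isotopes: pd.DataFrame,
                 config: CisiConfig | None = None) -> list[CisiResult]:
    """Score a batch of samples.

    ``chemistry`` columns: ``sample_id`` plus the configured chemical
    parameters; ``isotopes`` columns: ``sample_id``, ``r206_207``,
    ``r208_207``.  Min/max for the chemical indices come from the batch
    unless the config fixes external reference ranges.  Results carry a
    dense rank (1 = highest CISI).
    """
    config = config or CisiConfig()
    missing = [p for p in config.chemical_parameters
               if p not in chemistry.columns]
    if missing:
        raise KeyError(f"chemistry table lacks parameter column(s) {missing}")
    merged = chemistry.merge(isotopes, on="sample_id", validate="one_to_one")
    if merged.empty:
        raise ValueError("no overlapping samples between chemistry and isotopes")
    ranges = {}
    for p in config.chemical_parameters:
        if config.reference_ranges and p in config.reference_ranges:
            ranges[p] = config.reference_ranges[p]
        else:
            ranges[p] = (float(merged[p].min()), float(merged[p].max()))
    results = []
    for _, row in merged.iterrows():
        ci = {p: chemical_index(float(row[p]), *ranges[p])
              for p in config.chemical_parameters}
        ii = {"r206_207": isotopic_index(float(row["r206_207"]),
                                         config.r206_207_ref, config.clamp_ii),
              "r208_207": isotopic_index(float(row["r208_207"]),
                                         config.r208_207_ref, config.clamp_ii)}
        results.append(compute_cisi(ci, ii, config, str(row["sample_id"])))
    order = np.argsort([-r.cisi for r in results], kind="stable")
    for rank, idx in enumerate(order, start=1):
        results[idx].rank = rank
    return results


def validate_pca(features: pd.DataFrame, n_components: int | None = None):
    """PCA over the CI/II feature matrix (z-scored), as a structural check
    that a few components capture most between-sample variance.

    Returns ``(explained_variance_ratio, loadings, scores)``; loadings are
    orthonormal columns with a deterministic sign convention (largest-
    magnitude element of each component positive).  Rank-deficient input
    yields fewer components with a warning.
    """
    x = features.to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples for PCA validation")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features for PCA validation")
    keep = x.std(axis=0) > 0
    if not keep.all():
        warnings.warn("dropping zero-variance feature(s) before PCA",
                      stacklevel=2)
        x = x[:, keep]
    z = StandardScaler().fit_transform(x)
    rank = np.linalg.matrix_rank(z)
    k = min(n_components or z.shape[1], z.shape[1], x.shape[0] - 1)
    if rank < k:
        warnings.warn(f"feature matrix rank {rank} < requested components "
                      f"{k}; reducing", stacklevel=2)
        k = rank
    pca = PCA(n_components=k)
    scores = pca.fit_transform(z)
    loadings = pca.components_.T  # columns are components
    # deterministic sign: largest-|.| element of each component positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    # full variance fractions (sum to 1 over all retained + discarded)
    evr = pca.explained_variance_ratio_
    return evr, loadings, scores


def sensitivity_weights(ci_means, ii_means, weight_grid=None) -> pd.DataFrame:
    """CISI across a grid of (w1, w2) weight pairs, with the between-sample
    variance of the resulting scores per pair.

    The published weights were chosen by a sensitivity analysis whose
    procedure is unspecified; the documented surrogate here is a grid search
    reporting, for each weight pair summing to one, the spread the pair
    induces across samples (variance maximisation favours discriminating
    weightings).
    """
    ci = np.asarray(ci_means, dtype=float)
    ii = np.asarray(ii_means, dtype=float)
    if ci.shape != ii.shape:
        raise ValueError("ci_means and ii_means must align")
    if weight_grid is None:
        w1s = np.round(np.linspace(0.0, 1.0, 11), 10)
        weight_grid = [(w1, 1.0 - w1) for w1 in w1s]
    rows = []
    for w1, w2 in weight_grid:
        if abs(w1 + w2 - 1.0) > 1e-9:
            raise ValueError(f"grid weights must sum to 1, got ({w1}, {w2})")
        scores = w1 * ci + w2 * ii
        rows.append({"w_chemical": w1, "w_isotopic": w2,
                     "cisi_variance": float(np.var(scores)),
                     **{f"cisi_{i}": float(s) for i, s in enumerate(scores)}})
    return pd.DataFrame(rows)
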