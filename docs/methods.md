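# Methods

This note documents the models implemented in `soilrisk`, the parameter
choices that matter, the numerical conventions, and what the synthetic-data
generator does and does not emulate. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Ecological risk (Hakanson)

`Er = Tr · C / Cn` per element; `RI = Σ Er`. Reference concentrations `Cn`
default to the upper-continental-crust row used by the source survey
(Zn 31, Cu 29, Ni 20, Pb 15, Cr 35, Cd 0.09, As 4.8 mg/kg) and
toxic-response factors to Zn 1, Cu 5, Ni 5, Pb 5, Cr 2, Cd 30, As 10.
The survey's own threshold table is typographically garbled, so the standard
Hakanson bands are used (Er: 40/80/160/320; RI: 150/300/600), which match the
survey's prose conclusions. Boundaries are lower-inclusive: a value exactly
on a threshold takes the higher class.

The survey prints its Cd range both as 0.1–6.24 and 0.19–1.6 mg/kg; the
registry adopts 0.19/1.6 because the survey's own tabulated Er extrema
(63.33, 533.33) back-solve exactly from those with Cn = 0.09. Its tabulated
mean Er for Cd (91.32) is inconsistent with Tr·mean/Cn = 30·0.24/0.09 = 80;
both numbers are recorded in the registry provenance and neither is forced.

## Human health risk (PTEs)

Doses follow the USEPA residential-soil framework. Two named exposure
profiles exist:

- **PTE profile** (hazard/cancer assessment of elements): child/adult
  IngR 200/100 mg·day⁻¹, InhR 7.6/20 m³·day⁻¹, EF 350 d·yr⁻¹, ED 6/30 yr,
  SA 2800/3300 cm², AF 0.2/0.7 mg·cm⁻², ABF 0.001, BW 15/70 kg, CF 10⁻⁶
  kg·mg⁻¹, PEF 1.36×10⁹ m³·kg⁻¹, AT = 365·ED d (non-carcinogenic) or
  25 550 d (carcinogenic).
- **ILCR profile** (PAH cancer risk): child/adult BW 15/61.5 kg, EF 180,
  ED 6/24 yr, IR_ing 200/100, IR_inh 10/20, SA 2800/5700 cm², AF 0.2/0.07,
  ABS 0.13, AT = 25 550 d for both.

The adult skin-surface values differ between the two profiles on purpose:
each reproduces the parameter set its index was published with. The
adherence factor is treated as a per-event daily value (one event/day), the
standard convention, despite being labelled per hour in places upstream.

The published inhalation-dose expression contains the ingestion rate and the
kg/mg conversion factor; both double-count the m³→kg conversion already done
by the particle emission factor. The default is the dimensionally consistent
form `C·InhR·EF·ED/(PEF·BW·AT)`; `strict_published_formulas=True` evaluates the
printed expression verbatim for comparison. Because the upstream study never
prints the RfD and SF values behind its hazard table, its HQ/CR numbers are
not reproducible from stated inputs; the package ships a configurable
IRIS-style toxicity table and asserts only structural properties (linearity,
receptor orderings, pathway sums) plus an independently hand-evaluated
ingestion-ILCR value (9.18×10⁻⁵ at the survey-mean TEQ of 73.55 µg/kg,
child receptor). The corresponding published table prints 1.8×10⁻⁴, which
is not recoverable from its stated formula and parameters; the published
dermal values (2.51×10⁻⁴ adult, 2.25×10⁻⁴ child) *are* recovered by the
dermal formula, supporting the formula reading used here.

## PAH toxicity and ecosystem risk

TEQ uses the survey's tabulated TEF column (including its nonstandard
BaA = 0.001) as the default `"study"` set; the standard Nisbet–LaGoy set is
selectable as `"nisbet-lagoy"`. Below-detection compounds (BaP and BghiP in
the emulated survey) are a distinct ND state, excluded from sums by default;
a half-LOD substitution is available when the caller supplies LODs.

Risk quotients divide concentrations by negligible (NC) and
maximum-permissible (MPC = 100·NC for all tabulated compounds) benchmarks;
for the five compounds the survey benchmarks by TEF surrogacy, the registry
stores the surrogate values directly. Cumulative ΣPAH quotients sum only
terms ≥ 1. Classification grid: both < 1 risk-free/negligible; RQ(NC) ≥ 1
with RQ(MPC) < 1 low-to-moderate; RQ(MPC) ≥ 1 high. The ΣPAH grid's
overlapping boundary at exactly (ΣNC = 800, ΣMPC ≥ 1) resolves to the
higher class.

Two internal inconsistencies in the upstream tables are recorded and not
forced: the tabulated ΣRQ values (363.1 / 3.663) are not the sums of the
tabulated per-compound column (365.2 / 2.601 under the ≥ 1 rule), and the
tabulated BbF quotient implies a mean concentration (356.5 µg/kg) that
contradicts the narrative value (51.356 µg/kg). The registry stores the
narrative BbF mean; per-compound quotients, not the Σ rows, form the tested
surface.

## Pb-isotope mixing model

End-members: geogenic R1 = 1.2252, C1 = 6681 mg/kg; industrial R2 published
as a range 1.1427–1.1567 (default: midpoint 1.1497, overridable, with a
sweep helper); traffic R3 = 1.097. The industrial concentration is printed
both as 2397 and 2379 mg/kg — 2397 (first occurrence) is the default and the
alternate is selectable; the traffic concentration duplicates the industrial
one, as printed. The concentration constraint is harmonic
(`ΣFi/Ci = 1/C_soil`) exactly as specified upstream; the conventional linear
mass balance is available behind `concentration_rule="linear"` but never the
default.

The 3×3 system is solved exactly (`numpy.linalg.solve`); the solver reports
the condition number, and observations outside the triangular mixing
envelope yield `feasible=False` with diagnostics rather than clipped
fractions (Euclidean simplex projection is opt-in). The overdetermined
variant adds a ²⁰⁸Pb/²⁰⁷Pb balance and minimises the scaled residual with
the sum-to-one constraint eliminated analytically. No ²⁰⁸Pb/²⁰⁷Pb source
signatures are published, so synthetic defaults (2.476/2.41/2.38) are
shipped for that solver and the generator; they are labelled synthetic and
affect nothing in the default 206/207 path.

The published per-sample fraction table is kept as a constants fixture; its
column means (25.8/51.3/22.9 %) contradict the narrative means
(24.2/38.5/37.3 %), so only the sum-to-one invariant of those rows is
asserted.

## CISI

Chemical indices use standard min–max scaling
`CI = (X − Xmin)/(Xmax − Xmin)`. The upstream formula is printed as the
reciprocal, which is unbounded as X approaches Xmin; since every published
CI lies in [0,1] with the maximum-valued sample scoring exactly 1.0000, the
printed form is treated as a typo. Min/max default to the analysed batch;
fixed external reference ranges are configurable. Out-of-range values clamp
with a warning.

Isotopic indices `II = 1 − |R − R_ref|/R_ref` against references 1.2
(²⁰⁶Pb/²⁰⁷Pb) and 2.5 (²⁰⁸Pb/²⁰⁷Pb) are not clamped by default — the
published low-impact sample's indices (0.1675, 0.5316) imply relative
deviations of 83 % and 47 %, physically implausible for Pb ratios but
implemented as printed; a clamp option exists for strict boundedness.

Aggregation: `CISI = w1·C̄I + w2·ĪI`, defaults w = (0.6, 0.4). The upstream
weight choice is attributed to an unspecified sensitivity analysis; the
package provides a documented surrogate — a grid over weight pairs summing
to one, reporting the between-sample variance each pair induces. PCA
validation z-scores the CI/II feature matrix, fixes component signs by
making each loading's largest-magnitude element positive, and reduces the
component count with a warning on rank-deficient input. The upstream "65 %
of total variance" figure depends on unavailable per-sample supplementary
data and is not a target.

## Synthetic survey generator

The generator's defaults are the study conditions: 53 samples; per-element
truncated lognormals calibrated to the survey's mean/sd and truncated to its
observed min/max, with the lognormal location root-found so the *truncated*
mean equals the target exactly (the scale comes from the untruncated cv, so
the generated sd is somewhat below the nominal target — the price of honest
truncation); pH uniform over the survey range; per-compound lognormal PAHs
with exactly matched means and spread chosen so the survey's observed
maximum sits near the 1 − 1/53 quantile; BaP/BghiP injected as ND; isotope
surveys drawn as Dirichlet fractions (α = (2.6, 5.1, 2.3), matching the mean
mix of the published fraction table at moderate concentration) pushed
through the forward mixing model, with optional multiplicative noise and the
ground truth returned.

Deliberately not emulated: inter-element correlations (none are published),
spatial autocorrelation, and land-use-conditional concentration shifts
beyond the categorical mixture weights. The published compound means sum to
≈ 544 µg/kg while the published Σ15PAH mean is 850.81 µg/kg with a maximum
of 2460.87; the generator is calibrated to the compound means, so its
per-sample totals undershoot that printed range. Consequently, passing tests
demonstrate correctness of the computational chain under the published
marginal distributions, not fidelity to the unpublished joint structure of
the real survey.

Seeding: one top-level seed spawns independent substreams
(`numpy.random.SeedSequence`) for the element, PAH, isotope and land-use
draws, so each layer is reproducible in isolation.

## Problem sizes and numerics

Calibration checks use n = 5000 draws (relative tolerance 3 % for the Zn
mean, 5 % for Ant, comfortably above the CLT scale of the generators);
mixing round-trips use 200 Dirichlet draws at 10⁻⁹ absolute tolerance, and
noiseless fraction recovery is required below 10⁻⁸. Descriptive statistics
use the adjusted Fisher–Pearson sample skewness and unbiased excess
kurtosis (the survey's estimator is unstated, so its shape statistics are
not asserted); a constant vector yields flagged-undefined shape statistics
rather than NaN. Full float precision is preserved in all stored outputs;
display rounding (Er 2 dp, RQ 3 dp, CISI 4 dp) happens only in the CLI
layer.

## Known limitations

- Hazard quotients and cancer risks for PTEs depend entirely on the
  user-configurable RfD/SF table; the shipped defaults are conventional, not
  survey-specific.
- The mixing model supports exactly three end-members and inherits the
  published harmonic concentration constraint; with noisy ratios near the
  envelope boundary, small perturbations can flip feasibility (the condition
  number is reported for this reason).
- CISI scores are batch-relative unless external reference ranges are fixed:
  adding a sample can change every rank.
- ND handling is a policy choice (zero / half-LOD / exclude); results near
  detection limits are sensitive to it.
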