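# soilrisk

Risk assessment of urban soils contaminated by potentially toxic elements
(PTEs) and polycyclic aromatic hydrocarbons (PAHs), with Pb-isotope source
apportionment and a composite contamination index. The package targets
environmental scientists working with geochemical survey tables (per-sample
element concentrations, PAH profiles, Pb isotope ratios) who need the full
chain from raw CSV to graded risk reports.

It implements, as a tested reusable library:

- **Ecological risk (Hakanson).** Single-element risk factor
  `Er = Tr · C / Cn` (toxic-response factor × concentration over crustal
  background) and the summed risk index `RI = Σ Er`, with the standard
  grading bands (Er < 40 low … ≥ 320 very high; RI < 150 low … ≥ 600 high).
- **Human health risk (USEPA framework).** Average daily doses for soil
  ingestion, particle inhalation and dermal contact,
  `ADD_ing = C·IngR·CF·EF·ED/(BW·AT)` etc., hazard quotients `HQ = ADD/RfD`,
  hazard index `HI = Σ HQ`, and carcinogenic risk
  `CR = (ADD_ing + ADD_inh + ADD_derm)·SF`, for adult and child receptors.
- **PAH toxicity.** Benzo[a]pyrene equivalents `BaPeq_i = C_i·TEF_i`, their
  sum TEQ, incremental lifetime cancer risk per pathway (with the
  `∛(BW/70)` body-weight rescaling of the BaP slope factors), effects-range
  (ERL/ERM) screening, and LMW/HMW/carcinogen composition summaries.
- **PAH ecosystem risk.** Risk quotients `RQ = C/NC` and `RQ = C/MPC`
  against negligible and maximum-permissible benchmarks, cumulative ΣPAH
  quotients restricted to compounds with RQ ≥ 1, and the two-tier
  classification grid.
- **Pb-isotope mixing.** A three-end-member model (geogenic, industrial,
  traffic) solving `F1+F2+F3 = 1`, `ΣFi·Ri = R_soil`,
  `ΣFi/Ci = 1/C_soil` exactly, plus a sum-constrained least-squares variant
  using both ²⁰⁶Pb/²⁰⁷Pb and ²⁰⁸Pb/²⁰⁷Pb, feasibility diagnostics, and a
  sensitivity sweep over the industrial end-member's uncertainty range.
- **Combined Isotopic Impact Index (CISI).** Min–max-scaled chemical
  indices, isotopic deviation indices `II = 1 − |R − R_ref|/R_ref`, the
  weighted aggregate `CISI = w1·C̄I + w2·ĪI` (defaults 0.6/0.4), batch
  ranking, PCA validation and a weight-sensitivity grid.
- **Synthetic survey generator.** Seeded truncated-lognormal element and
  lognormal PAH generators calibrated to the study's summary statistics, and
  isotope surveys forward-mixed from Dirichlet source fractions with ground
  truth returned for recovery experiments.

## Worked example

```python
from soilrisk import SoilSample, ParameterRegistry
from soilrisk.eco_risk import assess_sample

soil = SoilSample("survey-mean", {
    "Zn": 125.55, "Cu": 56.83, "Ni": 56.19, "Pb": 27.04,
    "Cr": 111.47, "Cd": 0.24, "As": 4.62})
result = assess_sample(soil, ParameterRegistry())
for el, er in sorted(result.er.items(), key=lambda kv: -kv[1]):
    print(f"{el:>4} Er={er:7.2f} {result.er_grade[el].value}")
print(f"RI = {result.ri:.2f} ({result.ri_grade.value})")
```

prints

```
  Cd Er=  80.00 considerable
  Ni Er=  14.05 low
  Cu Er=   9.80 low
  As Er=   9.63 low
  Pb Er=   9.01 low
  Cr Er=   6.37 low
  Zn Er=   4.05 low
RI = 132.90 (low)
```

Cadmium dominates because its toxic-response factor (30) amplifies even a
modest 0.24 mg/kg against the 0.09 mg/kg crustal background, yet the summed
index stays below the 150 threshold: the mean urban soil is low-risk overall
with one element of considerable individual concern.

The `examples/` directory holds one narrative script per capability
(`ecological_risk.py`, `health_risk.py`, `pah_assessment.py`,
`pb_source_apportionment.py`, `cisi_index.py`, `synthetic_survey.py`); each
builds a small input, runs the method and explains the numbers it prints.

A thin CLI covers the same pipeline for shell use:

```bash
soilrisk simulate --n 53 --seed 7 --out survey/
soilrisk report --pte survey/pte.csv --pah survey/pah.csv \
    --isotopes survey/isotopes.csv --out report/
```

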