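"""Generate a seeded 53-sample synthetic survey and run every stage on it.

The generator reproduces the study conditions: truncated-lognormal element
concentrations matched to the survey's per-element mean/spread/range,
lognormal PAHs matched to the survey compound means, and isotope ratios
forward-mixed from Dirichlet-drawn source fractions (returned as ground
truth).
"""

import numpy as np

from soilrisk.pb_mixing import solve_mix
from soilrisk.synthetic_data import GeneratorSpec, generate_survey

spec = GeneratorSpec(n_samples=53, seed=7)
soil, pah, iso, truth = generate_survey(spec)

zn = np.mean([s.pte["Zn"] for s in soil])
ant = np.mean([p.pah["Ant"] for p in pah])
print(f"generated {len(soil)} samples (seed {spec.seed})")
print(f"Zn mean {zn:.1f} mg/kg (survey target 125.55)")
print(f"Ant mean {ant:.1f} µg/kg (survey target 141.02)")

errors = []
for m, f in zip(iso, truth):
    res = solve_mix({"r206_207": m.ratios["r206_207"], "c_pb": m.pb_conc})
    errors.append(np.abs(np.array(res.fractions) - f).max())
print(f"max source-fraction recovery error (noiseless): {max(errors):.2e}")

mean_f = truth.mean(axis=0)
print(f"mean true fractions: geogenic {mean_f[0]:.1%}, "
      f"industrial {mean_f[1]:.1%}, traffic {mean_f[2]:.1%}")
print("\nAt n=53 the sample means wander a few percent around the targets;"
      "\nthe mixing inversion is exact because the generator and solver share"
      "\nthe same three-equation model — noise knobs (ratio_noise, conc_noise)"
      "\nturn that into a realistic recovery experiment.")
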