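"""Combined Isotopic Impact Index over a small batch, with PCA validation.

Chemical parameters are min–max scaled within the batch; isotopic indices
measure closeness of the Pb ratios to reference values (1.2 and 2.5); the
CISI is their 0.6/0.4 weighted mean.
"""

import pandas as pd

from soilrisk.cisi import CisiConfig, assess_batch, validate_pca

chem = pd.DataFrame({
    "sample_id": ["A", "B", "C", "D", "E"],
    "pH": [7.2, 8.1, 8.4, 7.9, 8.8],
    "Pb": [12.0, 85.0, 40.0, 128.0, 22.0],
})
iso = pd.DataFrame({
    "sample_id": ["A", "B", "C", "D", "E"],
    "r206_207": [1.21, 1.12, 1.17, 1.10, 1.20],
    "r208_207": [2.48, 2.40, 2.44, 2.38, 2.47],
})

cfg = CisiConfig(chemical_parameters=("pH", "Pb"))
results = assess_batch(chem, iso, cfg)

print(f"{'sample':>7} {'C̄I':>7} {'ĪI':>7} {'CISI':>7}  rank")
for r in results:
    print(f"{r.sample_id:>7} {r.ci_mean:7.4f} {r.ii_mean:7.4f} "
          f"{r.cisi:7.4f}  {r.rank}")

features = pd.DataFrame([{**r.ci, **r.ii} for r in results])
evr, loadings, _ = validate_pca(features)
print(f"\nPCA explained-variance fractions: "
      f"{', '.join(f'{v:.1%}' for v in evr)}")
print("\nHigher CISI = more chemical enrichment and/or larger isotopic"
      "\ndeviation from the reference ratios; rank 1 is the most impacted"
      "\nsample in the batch.  A few dominant components in the PCA confirm"
      "\nthe index aggregates correlated contamination signals.")
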