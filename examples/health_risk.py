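"""Human-health hazard and cancer risk from soil Pb and As.

Computes average daily doses over the ingestion / inhalation / dermal
pathways for adult and child receptors, hazard quotients against reference
doses, the summed hazard index, and (where a slope factor exists) the
carcinogenic risk band.
"""

from soilrisk.health_risk_pte import assess_element

for element, c in (("Pb", 27.04), ("As", 4.62)):  # survey means, mg/kg
    print(f"\n{element} at {c} mg/kg")
    for receptor in ("adult", "child"):
        res = assess_element(c, element, receptor)
        hq = ", ".join(f"{p}={v:.2e}" for p, v in res.hq.items())
        line = f"  {receptor:>5}: HQ {hq}; HI={res.hi:.2e}"
        if res.cr is not None:
            line += f"; CR={res.cr:.2e} ({res.cr_band.value})"
        print(line)

print("\nHI < 1 means no expected non-carcinogenic effect; children score"
      "\nhigher than adults on ingestion (200 vs 100 mg soil/day on a 15 vs"
      "\n70 kg body).  CR between 1e-6 and 1e-4 is the conventionally"
      "\nacceptable lifetime cancer-risk range.")
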