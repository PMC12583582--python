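"""PAH toxicity and ecosystem risk for the survey-mean compound profile.

Converts per-compound concentrations to benzo[a]pyrene equivalents (TEQ),
estimates incremental lifetime cancer risk for both receptors, screens
against effects-range benchmarks, and computes negligible / maximum-
permissible risk quotients with the two-tier classification.
"""

from soilrisk.constants import SURVEY_PAH_MEANS
from soilrisk.core_data import PAHProfile
from soilrisk.pah_rq import assess_profile
from soilrisk.pah_tox import (composition_summary, compute_ilcr, compute_teq,
                              screen_erl_erm)

profile = PAHProfile("survey-mean", {**SURVEY_PAH_MEANS,
                                     "BaP": None, "BghiP": None})

teq = compute_teq(profile)
print(f"TEQ = {teq.teq:.2f} µg/kg BaP-equivalent "
      f"({teq.teq_fraction:.1%} of ΣPAH mass)")

for receptor in ("child", "adult"):
    ilcr = compute_ilcr(teq.teq, receptor)
    pw = ", ".join(f"{p}={v:.2e}" for p, v in ilcr.ilcr.items())
    print(f"ILCR {receptor}: {pw}; total={ilcr.total:.2e}")

screen = screen_erl_erm(profile)
exceeding = [c for c, s in screen.items() if s.value == "possible"]
print(f"\ncompounds between ERL and ERM (possible effects): {exceeding}")

comp = composition_summary(profile)
print(f"LMW fraction {comp['lmw_fraction']:.1%}, "
      f"carcinogenic fraction {comp['carcinogenic_fraction']:.1%}")

rq = assess_profile(profile)
print(f"\nΣRQ(NC) = {rq.sum_rq_nc:.1f}, ΣRQ(MPC) = {rq.sum_rq_mpc:.3f} "
      f"→ {rq.cumulative_class.value}")
high = [c for c, k in rq.individual_class.items() if k.value == "high"]
print(f"high-risk compounds (RQ(MPC) ≥ 1): {high}")
print("\nA compound above its negligible concentration but below the maximum"
      "\npermissible one is of low-to-moderate concern; above the MPC it"
      "\ncalls for remediation.")
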