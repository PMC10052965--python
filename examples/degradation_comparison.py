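"""Compare degradation energy-barrier profiles of a herbicide and substitute.

Loads the two-step hydrolysis-stage barrier pair (reference triazine
herbicide vs its designed substitute), prints per-step and total change
rates, and the 1:1 SOD+CAT fish-antioxidant toxicity composite.
"""

from herbiscreen import (
    SyntheticConfig,
    antioxidant_composite,
    compare_profiles,
    gen_energy_profiles,
)

ref, cand = gen_energy_profiles(SyntheticConfig())
report = compare_profiles(ref, cand)

print("step  reference dE   candidate dE   change rate")
for s in report["steps"]:
    print(f"{s['step']:>4}  {s['reference_delta_e']:>10.3f}   "
          f"{s['candidate_delta_e']:>10.3f}   {s['change_rate_pct']:+8.2f}%")
print(f"total {report['reference_total']:>10.3f}   "
      f"{report['candidate_total']:>10.3f}   "
      f"{report['total_change_rate_pct']:+8.2f}%")
print(f"verdict: candidate is {report['verdict']}")

tox = antioxidant_composite(sod=95.2, cat=88.4, reference_composite=210.0)
print(f"\nfish antioxidant composite (SOD+CAT, 1:1): {tox['composite']:.1f} "
      f"-> {tox['reduction_pct']:.2f}% below the reference herbicide")
print("Lower step barriers mean each hydrolysis step is easier, so negative "
      "change rates indicate a more readily degraded substitute; a lower "
      "SOD+CAT composite means weaker predicted inhibition of the fish "
      "antioxidant system, i.e. lower aquatic toxicity.")
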