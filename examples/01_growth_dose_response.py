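"""Dose-response growth assay: AUC per dose, inhibition profile, IC20.

Simulates a wild-type plate exposed to a geometric dose series of a
Hill-type toxicant (OD read every 15 min for 24 h, three replicates),
then estimates the IC20 — the concentration causing a 20% loss of
total growth (AUC) relative to the untreated wells.
"""

from fitscreen.growth import auc_table, correct_blanks, estimate_icx, inhibition_profile
from fitscreen.simulate import simulate_growth_doseresponse

plate, true_ic20 = simulate_growth_doseresponse(
    ic50=500.0, slope=1.5, doses=[0, 50, 100, 200, 400, 800, 1600], seed=42
)

per_well = auc_table(correct_blanks(plate))
profile = inhibition_profile(
    {dose: grp["auc"].to_list() for dose, grp in per_well.groupby("dose_uM")}
)
print(profile.to_frame().round(4).to_string(index=False))

est = estimate_icx(profile, 20)
print(f"\nestimated IC20 = {est.concentration:.1f} uM "
      f"(bracketed by {est.bracketing_doses} uM)")
print(f"true IC20 (Hill closed form) = {true_ic20:.1f} uM")
# The inhibition column is 1 - AUC(dose)/AUC(0); the IC20 is interpolated
# in (log10 dose, inhibition) between the two doses bracketing 0.20.
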