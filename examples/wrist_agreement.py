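"""Between-wrist agreement of the two count streams, by stroke severity.

Pools epochs within each severity stratum and reports the partial Pearson
correlation (controlling for participant), the consistency ICC(3,k) with its
95% CI, and Bland-Altman limits of agreement (affected minus non-affected).
"""

from wristcal import SimulationConfig, calibrate_all, simulate_cohort

profiles, epochs, _ = simulate_cohort(SimulationConfig(seed=7))
result = calibrate_all(epochs, profiles)

for stratum, rep in result.agreement.items():
    print(f"{stratum}: n={rep.n_epochs} epochs")
    print(f"  mean CPM affected {rep.mean_a:.0f} ({rep.sd_a:.0f}), "
          f"non-affected {rep.mean_b:.0f} ({rep.sd_b:.0f})")
    print(f"  partial r = {rep.partial_r:.2f}; "
          f"ICC(3,k) = {rep.icc:.2f} [{rep.icc_ci_low:.2f}, {rep.icc_ci_high:.2f}] "
          f"({rep.icc_category})")
    print(f"  Bland-Altman: mean diff {rep.ba_mean_diff:.0f} CPM, "
          f"limits [{rep.loa_low:.0f}, {rep.loa_high:.0f}]")

# A negative mean difference in the moderate-severe stratum reflects the
# hemiparetic wrist registering fewer counts than the non-affected wrist.
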