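"""Derive severity- and side-specific CPM cut-points on a synthetic cohort.

Simulates the default 43-participant laboratory session, then calibrates one
cut-point set per (stratum, side) cell: the sedentary bound maximizes the
Youden index J = Se + Sp - 100 in the low-count direction, the MVPA bound
maximizes J subject to a false-positive ratio <= 0.10.
"""

from wristcal import CalibrationConfig, SimulationConfig, calibrate_all, simulate_cohort

profiles, epochs, _ = simulate_cohort(SimulationConfig(seed=7))
result = calibrate_all(epochs, profiles, CalibrationConfig())

print(f"{'stratum':<16} {'side':<13} {'n':>5}  {'SB <=':>6}  {'MVPA >=':>7}  "
      f"{'J(SB)':>6}  {'J(MVPA)':>7}  {'Sp(MVPA)':>8}")
for s in result.cutpoints:
    print(
        f"{s.stratum:<16} {s.side:<13} {s.n_epochs:>5}  {s.sb_upper:>6.0f}  "
        f"{s.mvpa_lower:>7.0f}  {s.sb_metrics.youden_j:>6.2f}  "
        f"{s.mvpa_metrics.youden_j:>7.2f}  {s.mvpa_metrics.specificity:>7.1f}%"
    )

# Counts at or below "SB <=" score as sedentary, at or above "MVPA >=" as
# moderate-to-vigorous; the open band between is light activity.  MVPA
# specificity stays >= 90% by construction of the constrained optimizer.
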