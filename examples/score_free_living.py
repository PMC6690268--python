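"""Score a count stream with a published calibration.

Uses the mild-stroke affected-side cut-points (SB <= 134 CPM, MVPA >= 704 CPM)
to classify a short free-living stream and summarize time per intensity.
"""

from wristcal import CutPointSet, ThresholdMetrics, score_epochs, summarize_time

placeholder = ThresholdMetrics(
    threshold=0, sensitivity=0, specificity=100, accuracy=0,
    ppv=None, npv=None, youden_j=0,
)
mild_affected = CutPointSet(
    stratum="mild", side="affected", sb_upper=134, mvpa_lower=704,
    sb_metrics=placeholder, mvpa_metrics=placeholder,
)

stream = [12, 0, 85, 134, 135, 420, 560, 703, 704, 950, 1200, 88]
scored = score_epochs(stream, mild_affected)
for cpm, label in zip(stream, scored.labels):
    print(f"{cpm:>5} CPM -> {label.name}")
print(summarize_time(scored)["minutes"])

# Bounds are inclusive: 134 CPM is still sedentary, 704 CPM is already MVPA;
# everything strictly between is light activity.  One epoch = one minute.
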