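"""From measured energy expenditure to intensity classes.

Predicts basal metabolic rate from sex, age and weight, expresses a
calorimeter's per-minute energy rate in METs, and classifies the epoch.
"""

from wristcal import classify_intensity, mets_from_measurement, schofield_bmr

bmr_kcal_day = schofield_bmr("male", age=67, weight=80.0, units="kcal_per_day")
print(f"predicted BMR: {bmr_kcal_day:.0f} kcal/day")

for ee_kcal_min in (1.3, 2.2, 4.5, 7.0):
    mets = mets_from_measurement(ee_kcal_min, bmr_kcal_day)
    print(f"{ee_kcal_min:.1f} kcal/min -> {mets:.2f} METs -> {classify_intensity(mets).name}")

# METs express the measured rate as a multiple of the basal rate per minute;
# < 1.5 is sedentary, 1.5-3.0 light, > 3.0 moderate-to-vigorous.
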