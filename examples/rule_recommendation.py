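"""Rule-based treatment advice for single glucose observations.

The rule set maps the hour of day and the blood-sugar reading to one of
five actions through time-windowed thresholds: emergency rest below
70 mg/dL always wins; fasting-window readings over 126 mg/dL call for
exercise; low readings before sleep or four hours after a meal call for
eating; readings over 180 mg/dL at uncovered hours call for insulin.
"""

from glucoguide import ObservationRecord, recommend

observations = [
    (19, 300),  # evening spike at an hour no window covers
    (7, 50),    # dangerously low at breakfast time
    (11, 75),   # low in the late-morning post-meal window
    (23, 100),  # low-ish right before sleep
    (12, 113),  # unremarkable noon reading
]

for hour, blood_sugar in observations:
    record = ObservationRecord(
        time=hour, blood_sugar=blood_sugar, systolic=140, diastolic=70,
        exercise=0, meal=0, target_calories=1500,
    )
    code = recommend(record)
    print(f"hour {hour:>2}, blood sugar {blood_sugar:>3} mg/dL "
          f"-> treatment {int(code)}: {code.description}")

print()
print("Codes: 1 more exercise, 2 eat more, 3 rest (emergency), "
      "4 take insulin, 5 maintain.")
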