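"""Daily calorie target from a patient's body information.

Standard weight is height squared times a sex factor (21 for women, 22 for
men), rounded up to a whole kilogram, then multiplied by the kcal/kg band
of the patient's activity class (light 25-30, normal 30-35, hard 35-40).
"""

from glucoguide import daily_calories, round_standard_weight, standard_weight

weight = standard_weight(1.65, "female")
rounded = round_standard_weight(weight)
target = daily_calories(rounded, "light")

print(f"standard weight      : {weight:.4f} kg")
print(f"rounded up           : {rounded} kg")
print(f"daily calorie target : {target:.0f} kcal (light activity, band lower bound)")
print()
print("A 1.65 m woman doing light activity should eat about "
      f"{target:.0f} kcal per day to hold her standard weight.")
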