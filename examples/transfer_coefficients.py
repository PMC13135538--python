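"""Evaluate gestation-dependent transfer coefficients.

Builds nothing: evaluates the packaged piecewise-linear parameterization
k = a*t + b (per day) at a few gestational days and prints how the uterine
uptake and the uteroplacental exchange grow as pregnancy progresses.
"""

from radonpreg import evaluate_packaged

print(f"{'day':>5} {'art.blood->uterus':>18} {'uterus->placenta':>17} {'cord->brain':>12} {'cord->adipose':>14}")
for day in (0, 105, 140, 175, 210, 245, 280):
    row = [
        evaluate_packaged("arterial-blood", "uterus", day),
        evaluate_packaged("uterus", "placenta", day),
        evaluate_packaged("venous-cord-blood", "fetal-brain", day),
        evaluate_packaged("venous-cord-blood", "fetal-adipose", day),
    ]
    print(f"{day:>5} " + " ".join(f"{v:>{w}.4g}" for v, w in zip(row, (18, 17, 12, 14))))

print()
print("Units: 1/day. Fetal-side coefficients are zero before day 105 (placental")
print("development); the cord-blood->adipose coefficient ramps in over days")
print("161-175 and then stays constant at 1.0e3/day to term.")
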