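"""Acute inhalation intake: how much radon reaches the fetus?

Simulates a unit (1 Bq) acute inhalation bolus at gestational day 200 and
prints the peak fetal-side activity as a fraction of intake, with the
breakdown between the placenta, cord blood and fetal tissues proper.
"""

from radonpreg import IntakeScenario, solve

result = solve(IntakeScenario.acute(day=200.0, amount_bq=1.0, route="inhalation"))

frac = result.fetal_fraction(inclusive=True)
i_peak = int(frac.argmax())
t_peak = result.times[i_peak] - 200.0

print(f"peak fetal-side fraction (placenta + cord + tissues): {frac.max():.3e} of intake")
print(f"peak fetal-tissue-only fraction:                      {result.fetal_fraction(False).max():.3e}")
print(f"time of peak: {t_peak * 24 * 60:.0f} minutes after intake")
print(f"placenta at peak:   {result.activity('placenta')[i_peak]:.3e} Bq")
print(f"cord blood at peak: {result.activity('venous-cord-blood')[i_peak] + result.activity('arterial-cord-blood')[i_peak]:.3e} Bq")
print(f"exhaled by day 5:   {result.exhaled[-1]:.4f} Bq, decayed: {result.decayed[-1]:.4f} Bq")
print()
print("Most of an acute intake is exhaled within the hour; the small fraction")
print("that crosses the uteroplacental interface peaks within minutes and is")
print("washed back out through the arterial cord blood.")
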