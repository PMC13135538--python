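# radonpreg

Compartmental biokinetics of inhaled ²²²Rn during pregnancy: a
physiologically based model of radon in the pregnant body and its transfer to
the fetus through the uteroplacental circulation. It is aimed at internal
dosimetry — the parent-gas kinetics computed here are the precursor for
progeny activity and fetal dose assessment in occupational and residential
radon exposure.

## Model

Activities A (Bq) over 24 compartments evolve as a time-varying linear system

    dA/dt = K(t) A + s(t),        λ = ln2 / 3.8235 d = 0.1813 day⁻¹,

where t is the gestational day (term at 280) and K(t) carries perfusion-
limited (Fick) transfer coefficients plus radioactive decay:

    uptake   k(blood → tissue i) = F_i / V_blood-A
    washout  k(tissue i → blood) = F_i / (V_i · P_i)

with F_i the blood flow to tissue i, V volumes, and P_i the radon
tissue:blood partition coefficient (fat 11, bone 0.4, most soft tissues 0.7).
Because maternal and fetal physiology change across gestation, the
coefficients are packaged as piecewise-linear functions k = a·t + b of
gestational day. The fetal side (placenta, venous/arterial cord blood, nine
fetal tissues) activates at day 105, when the placenta is fully developed;
late-appearing compartments ramp in linearly (thyroid/marrow/"other" over
days 126–140, adipose over 161–175). Radon reaches the fetus only via
uterus → placenta → venous cord blood and returns via arterial cord blood →
placenta → uterus.

## Worked example

```python
from radonpreg import IntakeScenario, solve

result = solve(IntakeScenario.acute(day=200.0, amount_bq=1.0, route="inhalation"))
print(f"{result.fetal_fraction(inclusive=True).max():.3e}")   # 3.879e-03
print(f"{result.exhaled[-1]:.4f} / {result.decayed[-1]:.4f}") # 0.9948 / 0.0052
```

A 1-Bq acute inhalation at gestational day 200 sends at most 0.39 % of the
intake to the fetal side (placenta + cord blood + fetal tissues, peaking
about 3 minutes after intake); within 5 days 99.48 % has been exhaled and
0.52 % has decayed in the body. The chronic scenario of a 1 Bq/day infusion
over all of gestation (`examples/chronic_gestation.py`) ends with fetal
adipose tissue holding the largest radon content among fetal tissues
(2.18e-4 Bq, followed by red bone marrow at 2.75e-5 Bq) — radon is highly
fat-soluble and washes out of fat slowly.

More narrative scripts live in `examples/` (transfer coefficients across
gestation, acute and chronic scenarios, derivation cross-check), and a thin
CLI wraps the same library calls:

```sh
radonpreg validate            # parameter-table and coverage checks
radonpreg simulate --mode chronic --out out/
radonpreg derive              # Fick derivation vs packaged coefficients
radonpreg reproduce           # recompute the headline numbers
```

## Layout

- `src/radonpreg/` — `physiology` (gestational reference data),
  `rates` (Fick coefficients and the packaged parameterization),
  `model` (compartment graph and rate-matrix assembly),
  `simulate` (scenario integration), `report`, `cli`
- `src/radonpreg/data/` — parameter tables with a manifest and per-row
  provenance (`docs/data_dictionary.md`)
- `docs/methods.md` — model assumptions, parameters, numerics, limitations
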