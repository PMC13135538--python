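# Methods

## Model

`radonpreg` implements a linear compartmental biokinetic model of inhaled
²²²Rn in the pregnant body and its transfer to the fetus. The state is the
vector of compartment activities A (Bq) over 24 compartments — the maternal
systemic model (lung air, arterial and venous blood, Fat 1/Fat 2, glandular
and adipose breast, kidneys, liver, uterus, an aggregated "other" pool, and an
absorbing exhaled-air sink) plus, from gestational day 105, the placenta,
venous and arterial cord blood, and nine fetal tissues (lungs, brain, kidneys,
thyroid, bone, red bone marrow, liver, adipose, "other"). The dynamics are

    dA/dt = K(t) A + s(t)

with gestational day t (days since conception, term at t = 280), source s for
the intake, and rate matrix K whose off-diagonal (j, i) is the transfer
coefficient k(i→j) (day⁻¹) and whose diagonals balance the column outflows
plus the ²²²Rn decay constant λ = ln 2 / 3.8235 d = 0.18129 day⁻¹.

Transfer coefficients follow perfusion-limited (Fick) gas kinetics: tissue
uptake from a blood pool is k = F/V_blood and washout back to blood is
k = F/(V_tissue · P), with F the tissue blood flow (l/day), V volumes (l, at
unit tissue density), and P the radon tissue:blood partition coefficient
(fat 11; bone 0.4; kidney, liver, brain, lung 0.7; uterus muscle-like 0.4).
Fetal partition coefficients are taken equal to adult values, for lack of
fetal-specific data.

Radon reaches the fetus only along uterus → placenta → venous cord blood →
fetal tissues, and returns along fetal tissues → arterial cord blood →
placenta → uterus. The uteroplacental circulation is balanced: the volumetric
flow behind placenta→uterus equals the uterus→placenta flow at every day.

## Parameterization: two routes

The *packaged* parameterization — the one the simulator uses — is a table of
piecewise-linear regressions k = a·t + b per directed edge (one table for
maternal tissues, one for the placenta/cord/fetal side). Evaluation is
right-continuous at interior breakpoints, clipped at zero (a few segments
start marginally negative at their ramp-in day), clamped to the boundary
value outside the tabulated range for maternal edges, and identically zero
before the first segment for fetal-side edges (the compartment does not exist
yet). Late-appearing fetal compartments ramp in linearly — thyroid, red
marrow and "other" from day 126 to full value at 140, adipose from 161 to
175 — and these ramps are already encoded in the regression segments. The
packaged adipose-uptake row carries the 161–175 ramp segment (its tabulated
interval was corrected from a misprinted 126–140: the line crosses zero at
≈ day 161 and reaches ≈ 1.0·10³ at 175) followed by a constant
1.0·10³ day⁻¹ segment to term. Thyroid and red-marrow coefficients are
mass-ratio-scaled from the fetal "other" pool, which is defined as total
fetal mass minus the explicitly modelled organs (adipose included in the
subtraction only from day 161).

The *derivation* route recomputes coefficients from the physiology tables via
the Fick relations; it is an independent cross-check, not the simulation
path. Physiological inputs: pregnancy mass increments at weeks 10/20/30/38;
fetal organ masses at weeks 8–38; fetal organ flows at weeks 15/22/32/40;
uteroplacental flow anchored at (day 105, 350), (140, 513), (266, 970)
ml/min and held constant after 266; umbilical-vein flow linear between
(140, 50) and (280, 275) ml/min, extrapolated backward on [105, 140) and
floored at zero; fetal blood volume 16.2 ml per 100 g of fetal mass;
umbilical-artery flow 0.35 × combined fetal cardiac output (configurable
within the accepted 0.30–0.40 range). Everything between anchors is linearly
interpolated; outside an anchored range values are clamped, never
extrapolated (the umbilical vein being the one documented exception). Two
derivation inputs are calibration parameters rather than reference data: the
venous and arterial cord-blood volumes, taken as 0.17 and 0.20 of the total
fetal blood volume (chosen once so that back-calculated cord volumes match
the packaged uptake/return coefficients at weeks 32 and 40; ≈ 0.06 l and
0.07 l at week 32, 0.10 l and 0.11 l at term).

Agreement between the two routes is approximate by construction — the
packaged values are least-squares lines fitted through coefficients computed
at seven key gestational days, and the underlying inputs are not fully
recoverable. Measured: placenta→uterus agrees within 25 % at all key days;
cord→organ uptake within ~30 % (typically 15 %); uterus→placenta departs by
up to ~39 % at days 105–154, where back-calculation shows the two packaged
directions imply mutually inconsistent placental volumes, so no single
volume convention can match both. The package keeps the strict 25 % check in
its acceptance suite and lets the early-day uterus→placenta comparisons fail
rather than widen the band.

## Baseline maternal model and pregnancy adjustments

The non-pregnant adult-female constants live in an editable parameter file
with per-row provenance. Reference values: cardiac output 5.9 l/min rising
linearly to 7.3 l/min at term; blood 3.9 l split 1.1 l arterial / 2.8 l
venous (the arterial volume is fixed by consistency of the packaged
regression intercepts with reference flows: the kidney uptake intercept
1.33·10³ day⁻¹ equals 17 % CO / 1.1 l, and the uterus line at its first day
equals 0.4 % CO / 1.1 l); lung air 2.7 l (functional residual capacity);
alveolar ventilation 6 480 l/day.

Lung gas exchange is described in prose only in the source material, so its
edges are an interpreted reconstruction, flagged as such in the model
registry: venous blood feeds both arterial blood and lung air at CO/V_ven;
lung air feeds arterial blood at CO·λ_b:a/V_air (blood:air partition
λ_b:a = 0.43) and vents to the exhaled-air sink at V̇_A/V_air. The scheme
reproduces the blood:air equilibrium concentration ratio 0.43 exactly and
gives fast pulmonary washout (≈ 32 % of venous throughput exhaled per pass);
about 36 % of an acute inhaled bolus is absorbed into blood, the rest
exhaled.

Integrating the uterus as an explicit compartment requires removing its
contribution from the aggregated "other" pool: the arterial-blood→other
coefficient drops by F_uterus/V_arterial = 33.98/1.1 = 30.89 day⁻¹ to
5.02·10³ day⁻¹ and stays constant thereafter; other→liver and
other→venous-blood are unchanged. The packaged file stores the
pre-extraction value (reconstructed as the published post-extraction value
plus the uterine contribution, since the pre-extraction number is not
printed anywhere) and the extraction is recomputed at run time. Pregnancy
kidney adjustments: mass +30 % at term (linear), flow +80 % at day 105
rising from day 70, relaxing to +50 % at term. Maternal blood volumes are
held constant over pregnancy (flagged; plasma expansion is not modelled),
and the breast-increment split between glandular and adipose breast is a
configurable 0.5/0.5 (no reference split exists).

## Scenarios and solvers

Acute intakes are initial-value boluses (inhalation → lung air; injection →
arterial blood); chronic intakes are continuous infusions at a constant
Bq/day rate — "1 Bq administered daily" is modelled as a smooth 1 Bq/day
infusion. Default output grids: 0.002 day for the first half-day after an
acute bolus then 0.01 day out to 5 days (radon's 3.8-day half-life); 0.5 day
for chronic runs.

The adaptive solver (LSODA, rtol 1e-8, atol 1e-12 Bq) exploits that K(t) is
exactly linear in t between parameterization breakpoints: integration
proceeds chunk-by-chunk over the breakpoint set (segment bounds plus
zero-crossings of clipped lines), with the analytic Jacobian supplied. An
auxiliary accumulator integrates λ·ΣA over the body so that

    intake(t) = body(t) + exhaled(t) + decayed(t)

holds to solver tolerance (measured ≲ 1e-14 relative). A second,
algorithmically independent solver steps with the matrix exponential of the
midpoint rate matrix per step, folding constant sources in through the
augmented-matrix construction; it conserves mass to machine precision.
With physiology frozen at a fixed gestational day the stepping is exact and
the two solvers agree to ~2e-8 relative; with time-varying coefficients the
piecewise-constant stepping itself carries first-order discretization error
(measured 1.3e-3 at 0.1-day steps, 8e-5 at 0.01), so solver-accuracy checks
at the 1e-6 level are run in the constant-coefficient regime.

Numerical conventions: activities are clipped at zero on output (negative
excursions beyond −1e-7 of scale raise a warning); at shared segment
breakpoints the later segment applies; simulation past day 280 (the tail of
a near-term acute intake) holds all coefficients at their term values.

## Tested claims and known limitations

The acceptance suite recomputes: the uterus-extraction value 5.02·10³ day⁻¹
(exact); the constant cord→adipose coefficient 1.0·10³ day⁻¹ on [175, 280]
(exact); the packaged slopes (exact); the 12 500 g total weight gain at week
38 (exact); conservation, steady-state partition ratio (reduced
two-compartment model, ratio = 11 for fat), solver cross-validation; and the
chronic-exposure ordering — at term the fetal adipose compartment holds the
largest accumulated content among named fetal tissues with red bone marrow
second (2.18e-4 Bq vs 2.75e-5 Bq under 1 Bq/day). By *concentration* the
ordering differs: the mass-ratio-scaled thyroid coefficients give a washout
(0.21 day⁻¹ at term) slower than radioactive decay and hence an outsized
concentration — a known artifact of scaling a 1.3-g organ from the
aggregate pool; the content ordering is the robust statement and is the one
tested.

The published bound that at most 0.001 % of an acute intake reaches fetal
tissues is *not* reproduced: simulated peak fetal-side fractions run from
0.14 % (intake at day 105) to 0.93 % (day 280), ~100× the bound, and
tissues-only tallies are ~4× lower. The discrepancy is driven by the
packaged uteroplacental coefficients themselves (units of 10³ day⁻¹), which
move activity to the fetal side within minutes — far faster than decay
(λ = 0.18 day⁻¹) can compete with — and cannot be closed by any maternal
kinetics: even complete per-pass pulmonary exhalation lowers the fraction by
less than 3×. The corresponding acceptance test is left failing by design
rather than tuned; the chronic fractional tally (≈ 1.7e-6 of cumulative
intake) incidentally matches the claimed order of magnitude.

Other limitations: no radon progeny (²¹⁸Po/²¹⁴Pb/²¹⁴Bi) and no dose
coefficients — the model describes the parent gas only; no respiratory-tract
deposition model (air–blood equilibrium is assumed); a single adult-female
baseline (no age/sex series); maternal blood-volume expansion neglected;
before day 105 fetal exposure is by convention that of the uterus wall and
is not computed here.
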