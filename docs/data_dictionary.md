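# Data dictionary

Packaged tables under `src/radonpreg/data/`. `manifest.csv` records the
provenance of every file; `baseline_rates.csv` and `constants.csv` carry a
per-row provenance column.

## maternal_mass_gain.csv
Pregnancy mass increments over the non-pregnant baseline.

| column | type | meaning |
|---|---|---|
| tissue | str | `fetus`, `placenta`, `uterus`, `breasts`, `total` |
| day | float | gestational day of the anchor (0, 70, 140, 210, 266 = weeks 0/10/20/30/38) |
| increment_g | float | mass gained since conception, g |

A zero anchor at day 0 is included so interpolation starts at the baseline.

## maternal_blood_flow.csv
| column | type | meaning |
|---|---|---|
| quantity | str | tissue group, or `cardiac_output` |
| unit | str | `pct_cardiac_output` or `l_per_min` |
| nonpregnant / pregnant_term | float | reference value at day 0 / day 280 (linear between) |

## fetal_masses.csv
| column | type | meaning |
|---|---|---|
| organ | str | `brain`, `kidneys`, `liver`, `lungs`, `red-marrow`, `bone`, `thyroid`, `adipose`, `total-body` |
| day | float | anchor day (56–266 = weeks 8–38; adipose from week 25) |
| mass_g | float | organ mass, g |

## fetal_flows.csv
| column | type | meaning |
|---|---|---|
| organ | str | organ, `combined-cardiac-output`, or `umbilical-vein` |
| day | float | anchor day (105, 154, 224, 280 = weeks 15/22/32/40) |
| flow_l_per_h | float | mean blood flow, l/h |

## partition_coefficients.csv
`tissue`, `partition_coefficient` — dimensionless radon tissue:blood
equilibrium concentration ratios. `uterus`/`muscle`/`other` = 0.4 and
`placenta` = 1.0 are modeling conventions (see manifest).

## regressions_maternal.csv / regressions_fetal.csv
Piecewise-linear transfer-coefficient parameterization.

| column | type | meaning |
|---|---|---|
| from / to | str | compartment identifiers (see `model.yaml`) |
| t_start / t_end | float | gestational-day interval of the segment (contiguous per pair) |
| a | float | slope, day⁻¹ per day |
| b | float | intercept, day⁻¹ |

Evaluation: `max(a·t + b, 0)`, right-continuous at interior breakpoints;
maternal pairs clamp outside their range, fetal pairs are zero before their
first segment.

## baseline_rates.csv
Constant coefficients of the non-pregnant baseline: `from`, `to`,
`k_per_day`, `provenance`. `arterial-blood → other` is stored
*pre-extraction*; the uterus extraction is applied at load time.

## constants.csv
Scalar constants and configurable parameters: `name`, `value`, `unit`,
`provenance`. Includes the ²²²Rn half-life, blood/air volumes, partition of
blood:air, cord-blood volume fractions and the umbilical-artery fraction.

## model.yaml
Compartment registry (`id`, `group`, `active_from` day) and the directed edge
list with the parameterization source per edge (`baseline`,
`maternal-table`, `fetal-table`); lung-air edges are flagged
`interpreted: true`.
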