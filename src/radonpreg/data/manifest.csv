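file,contents,source
maternal_mass_gain.csv,"pregnancy mass increments (g) for fetus, placenta, uterus, breasts and total at weeks 10/20/30/38, with a zero anchor at conception","ICRP Publication 89, Table 12.2 (adapted)"
maternal_blood_flow.csv,"blood flow to fat, uterus, breast and 'other' as percent of cardiac output, non-pregnant vs pregnant near term, plus cardiac output","ICRP Publication 89, Table 2.44 (adapted)"
fetal_masses.csv,"fetal organ and total-body masses (g) at weeks 8-38; adipose from week 25 via lipid-content fractions","ICRP Publication 88, Table 2.3 and ICRP Publication 89 lipid content (adapted)"
fetal_flows.csv,"mean fetal organ blood flows (l/h) at weeks 15/22/32/40 including combined cardiac output and umbilical vein","Abduljalil et al., fetal PBPK reference data (adapted)"
partition_coefficients.csv,"radon tissue:blood partition coefficients; uterus and 'other' set to the muscle value 0.4, placenta treated as a blood-equivalent exchange compartment (P=1)","Leggett et al., noble-gas biokinetic review (adapted); muscle/placenta assignments are modeling conventions"
regressions_maternal.csv,"piecewise-linear gestational-age parameterization k = a*t + b (per day) of maternal transfer coefficients","packaged parameterization of the perfusion-limited model; fitted to coefficients derived from the physiology tables at the reference gestational days"
regressions_fetal.csv,"piecewise-linear gestational-age parameterization of placenta, cord-blood and fetal-organ transfer coefficients; venous-cord-blood>fetal-adipose carries a 161-175 ramp segment (interval corrected from a misprinted 126-140) plus a constant 1.0E+03 segment to term","packaged parameterization of the perfusion-limited model"
baseline_rates.csv,"constant transfer coefficients of the non-pregnant adult-female baseline (lung gas exchange, liver, aggregated 'other'); arterial-blood>other stored before uterus extraction","reconstructed from ICRP 89 reference flows/volumes and the partition coefficients; per-row provenance column"
constants.csv,"physical constants, reference volumes/flows and configurable model parameters","per-row provenance column"
model.yaml,"compartment registry with activation days and the directed edge list","model structure; lung-air edges flagged as interpreted"
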