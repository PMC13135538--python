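name,value,unit,provenance
rn222_half_life,3.8235,day,"standard nuclide data (DDEP); decay constant ln2/3.8235 = 0.181288 per day"
blood_air_partition,0.43,dimensionless,"radon blood:air partition coefficient (Leggett et al. noble-gas review)"
cardiac_output_nonpregnant,8496.0,l_per_day,"5.9 l/min, ICRP 89 adult female"
cardiac_output_term,10512.0,l_per_day,"7.3 l/min at term, ICRP 89"
alveolar_ventilation,6480.0,l_per_day,"4.5 l/min resting adult female"
uterine_flow_nonpregnant,33.984,l_per_day,"0.4 pct of non-pregnant cardiac output, ICRP 89"
volume_arterial_blood,1.1,l,"arterial share of 3.9 l total blood (ICRP 89); consistent with kidney uptake intercept 1.33E+03 = 17 pct CO / 1.1 and uterus uptake 30.9 = 0.4 pct CO / 1.1"
volume_venous_blood,2.8,l,"venous share of 3.9 l total blood, ICRP 89"
volume_lung_air,2.7,l,"functional residual capacity, adult female, ICRP 89"
volume_uterus_baseline,0.080,l,"non-pregnant uterus 80 g, ICRP 89; unit tissue density"
volume_fat1,8.9,l,"half of total separable adipose; model-consistent effective volume (washout intercept 5.93 = 579.7/(8.9 x 11))"
volume_fat2,8.9,l,"half of total separable adipose; equal Fat1/Fat2 volumes per the noble-gas convention"
volume_breast_g,0.149,l,"glandular breast, model-consistent effective volume"
volume_breast_a,0.101,l,"adipose breast, model-consistent effective volume"
volume_kidneys,0.275,l,"kidneys 275 g, ICRP 89 adult female"
volume_liver,1.4,l,"liver 1400 g, ICRP 89 adult female"
volume_other,36.2,l,"60 kg reference female minus blood, fat, breast, kidneys, liver, uterus"
fetal_blood_ml_per_100g,16.2,ml_per_100g,"fetal blood volume coefficient (umbilical venous studies)"
umbilical_artery_fraction,0.35,dimensionless,"fraction of combined fetal cardiac output returned to the placenta; midpoint of the accepted 30-40 pct range"
vcb_volume_fraction,0.17,dimensionless,"venous cord blood as a fraction of total fetal blood volume; calibration of the derivation path (gives 0.059 l at week 32, 0.096 l at term)"
acb_volume_fraction,0.20,dimensionless,"arterial cord blood as a fraction of total fetal blood volume; calibration of the derivation path"
breast_glandular_increment_fraction,0.5,dimensionless,"apportioning of the pregnancy breast-mass increment between glandular and adipose breast (configurable; no reference split available)"
tissue_density,1.0,g_per_ml,"unit density for mass-to-volume conversion of soft tissue"
partition_other_maternal,0.4,dimensionless,"muscle-equivalent partition for the aggregated maternal 'other' compartment"
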