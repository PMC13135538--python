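quantity,unit,nonpregnant,pregnant_term
fat,pct_cardiac_output,8.5,7.8
uterus,pct_cardiac_output,0.4,12.0
breast,pct_cardiac_output,0.4,3.5
other,pct_cardiac_output,3.2,3.3
cardiac_output,l_per_min,5.9,7.3
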