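tissue,partition_coefficient
fat,11
bone,0.4
kidney,0.7
liver,0.7
brain,0.7
lung,0.7
uterus,0.4
muscle,0.4
other,0.4
placenta,1.0
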