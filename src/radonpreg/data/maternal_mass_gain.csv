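tissue,day,increment_g
fetus,0,0
fetus,70,5
fetus,140,300
fetus,210,1500
fetus,266,3400
placenta,0,0
placenta,70,20
placenta,140,170
placenta,210,430
placenta,266,650
uterus,0,0
uterus,70,140
uterus,140,320
uterus,210,600
uterus,266,970
breasts,0,0
breasts,70,45
breasts,140,180
breasts,210,360
breasts,266,405
total,0,0
total,70,650
total,140,4000
total,210,8500
total,266,12500
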