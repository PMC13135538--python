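organ,day,mass_g
brain,56,3.7
brain,70,6.4
brain,105,22
brain,140,59
brain,175,118
brain,210,192
brain,266,352
kidneys,56,0.022
kidneys,70,0.12
kidneys,105,1.2
kidneys,140,3.5
kidneys,175,7.0
kidneys,210,12
kidneys,266,23
liver,56,0.19
liver,70,0.81
liver,105,6.1
liver,140,17
liver,175,35
liver,210,59
liver,266,120
lungs,56,0.081
lungs,70,0.53
lungs,105,4.9
lungs,140,12.0
lungs,175,22
lungs,210,32
lungs,266,51
red-marrow,56,0.065
red-marrow,70,0.28
red-marrow,105,2.2
red-marrow,140,6.5
red-marrow,175,12
red-marrow,210,23
red-marrow,266,47
bone,56,0.023
bone,70,0.1
bone,105,0.76
bone,140,2.2
bone,175,4.4
bone,210,7.3
bone,266,15
thyroid,56,0.011
thyroid,70,0.022
thyroid,105,0.077
thyroid,140,0.18
thyroid,175,0.36
thyroid,210,0.63
thyroid,266,1.3
total-body,56,4.8
total-body,70,21
total-body,105,160
total-body,140,480
total-body,175,1000
total-body,210,1700
total-body,266,3500
adipose,175,23.7
adipose,210,107.1
adipose,266,392
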