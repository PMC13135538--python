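organ,day,flow_l_per_h
combined-cardiac-output,105,1.52
combined-cardiac-output,154,11.91
combined-cardiac-output,224,49.87
combined-cardiac-output,280,84.63
umbilical-vein,105,0.408
umbilical-vein,154,2.820
umbilical-vein,224,9.619
umbilical-vein,280,13.35
liver,105,0.310
liver,154,2.420
liver,224,9.254
liver,280,14.02
brain,105,0.181
brain,154,1.652
brain,224,8.010
brain,280,14.81
lungs,105,0.336
lungs,154,2.620
lungs,224,10.97
lungs,280,18.62
adipose,105,0.076
adipose,154,0.595
adipose,224,2.49
adipose,280,4.232
kidneys,105,0.133
kidneys,154,0.934
kidneys,224,3.294
kidneys,280,4.753
bone,105,0.076
bone,154,0.595
bone,224,2.493
bone,280,4.232
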