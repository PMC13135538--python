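from,to,t_start,t_end,a,b
uterus,placenta,105,160.7,-2.10E+01,6.06E+03
uterus,placenta,160.7,210,6.11E+00,1.70E+03
uterus,placenta,210,224,-7.13E+01,1.80E+04
uterus,placenta,224,280,3.43E+00,1.21E+03
placenta,uterus,105,280,-1.95E+01,7.19E+03
placenta,venous-cord-blood,105,149.1,-9.61E-01,5.84E+02
placenta,venous-cord-blood,149.1,280,2.18E+00,1.15E+02
arterial-cord-blood,placenta,105,197.9,3.60E+01,-1.02E+03
arterial-cord-blood,placenta,197.9,280,-1.77E+00,6.45E+03
venous-cord-blood,fetal-lungs,105,198,2.63E+01,-7.32E+02
venous-cord-blood,fetal-lungs,198,280,-1.29E+00,4.73E+03
venous-cord-blood,fetal-brain,105,280,1.43E+01,-7.25E+01
venous-cord-blood,fetal-kidneys,105,198.5,6.26E+00,1.64E+02
venous-cord-blood,fetal-kidneys,198.5,280,-3.55E+00,2.11E+03
venous-cord-blood,fetal-thyroid,126,140,1.31E-02,-1.65E+00
venous-cord-blood,fetal-thyroid,140,280,7.00E-03,-7.96E-01
venous-cord-blood,fetal-bone,105,206.5,7.83E+00,-4.01E+02
venous-cord-blood,fetal-bone,206.5,280,-2.99E+00,1.83E+03
venous-cord-blood,fetal-bone-marrow,126,140,4.65E-01,-5.85E+01
venous-cord-blood,fetal-bone-marrow,140,280,2.71E-01,-3.14E+01
venous-cord-blood,fetal-liver,105,280,1.23E+01,1.02E+03
venous-cord-blood,fetal-other,126,140,4.79E+01,-6.04E+03
venous-cord-blood,fetal-other,140,280,1.62E+01,-1.59E+03
venous-cord-blood,fetal-adipose,161,175,7.14E+01,-1.15E+04
venous-cord-blood,fetal-adipose,175,280,0.0,1.0E+03
fetal-lungs,arterial-cord-blood,105,280,6.14E+01,3.11E+03
fetal-brain,arterial-cord-blood,105,280,7.16E+00,-3.13E+02
fetal-kidneys,arterial-cord-blood,105,197.4,4.12E+01,4.45E+02
fetal-kidneys,arterial-cord-blood,197.4,280,-1.49E+01,1.15E+04
fetal-adipose,arterial-cord-blood,161,175,7.11E+00,-1.15E+03
fetal-adipose,arterial-cord-blood,175,220.4,-1.49E+00,3.60E+02
fetal-adipose,arterial-cord-blood,220.4,280,-1.62E-01,6.78E+01
fetal-thyroid,arterial-cord-blood,126,140,2.90E-03,-3.65E-01
fetal-thyroid,arterial-cord-blood,140,280,1.20E-03,-1.27E-01
fetal-bone,arterial-cord-blood,105,207.3,2.30E+02,-1.37E+04
fetal-bone,arterial-cord-blood,207.3,280,-8.29E+01,5.12E+04
fetal-bone-marrow,arterial-cord-blood,126,140,9.35E-02,-1.18E+01
fetal-bone-marrow,arterial-cord-blood,140,280,4.64E-02,-5.19E+00
fetal-liver,arterial-cord-blood,105,198.9,2.07E+01,-2.27E+02
fetal-liver,arterial-cord-blood,198.9,280,-7.37E+00,5.36E+03
fetal-other,arterial-cord-blood,126,140,3.47E+00,-4.38E+02
fetal-other,arterial-cord-blood,140,280,2.67E+00,-3.25E+02
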