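from,to,t_start,t_end,a,b
arterial-blood,uterus,8.6,280,3.99E+00,-3.48E+00
uterus,venous-blood,0,68.7,6.36E+01,1.12E+03
uterus,venous-blood,68.7,280,-1.03E+01,6.19E+03
arterial-blood,fat1,0,280,2.54E-01,5.27E+02
fat1,venous-blood,0,280,-5.90E-03,5.93E+00
arterial-blood,fat2,0,280,6.34E-02,1.32E+02
fat2,venous-blood,0,280,-1.50E-03,1.48E+00
arterial-blood,breast-g,0,280,7.38E-01,1.03E+01
breast-g,venous-blood,0,280,1.44E+00,1.09E+02
arterial-blood,breast-a,0,280,4.43E-01,6.20E+00
breast-a,venous-blood,0,280,8.10E-02,6.15E+00
arterial-blood,kidneys,0,70,4.41E+00,1.33E+03
arterial-blood,kidneys,70,105,3.38E+01,-9.75E+02
arterial-blood,kidneys,105,154,2.00E+00,2.36E+03
arterial-blood,kidneys,154,210,-6.28E+00,3.64E+03
arterial-blood,kidneys,210,280,1.67E+00,1.97E+03
kidneys,venous-blood,0,70,-1.74E+00,8.36E+03
kidneys,venous-blood,70,105,1.85E+02,-4.74E+03
kidneys,venous-blood,105,154,-2.61E+00,1.50E+04
kidneys,venous-blood,154,210,-4.54E+01,2.16E+04
kidneys,venous-blood,210,280,-1.76E+00,1.24E+04
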