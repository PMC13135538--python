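from,to,k_per_day,provenance
lung-air,arterial-blood,1353.0667,"gas uptake at the alveolar interface: CO x P_blood:air / V_lung-air = 8496 x 0.43 / 2.7; interpreted reconstruction of the prose lung model (air-blood equilibrium assumption)"
venous-blood,arterial-blood,3034.2857,"pulmonary blood transit: CO / V_venous = 8496 / 2.8 (ICRP 89 adult-female cardiac output and venous blood volume)"
venous-blood,lung-air,3034.2857,"gas loss to alveolar air during pulmonary transit: CO / V_venous; paired with lung-air>arterial-blood it yields the equilibrium blood:air concentration ratio 0.43"
lung-air,exhaled-air,2400.0,"ventilatory washout: alveolar ventilation / V_lung-air = 6480 / 2.7 (resting adult female)"
arterial-blood,liver,502.0364,"hepatic arterial uptake: 6.5 pct CO / V_arterial = 552.24 / 1.1 (ICRP 89 adult female)"
arterial-blood,other,5050.89454545455,"aggregated 'other' tissues before uterus extraction; reconstructed as the published post-extraction value 5.02E+03 plus the uterine contribution F_ut/V_art = 33.984/1.1 = 30.8945 (non-pregnant uterine flow 0.4 pct CO, ICRP 89)"
liver,venous-blood,2340.7347,"hepatic washout: (hepatic artery + portal flow) / (V_liver x P_liver) = 2293.92 / (1.4 x 0.7)"
other,venous-blood,263.4188,"direct venous return of 'other': (F_other - portal) / (V_other x P_other) = 3814.3 / (36.2 x 0.4)"
other,liver,120.2818,"portal flow routed through the liver: 20.5 pct CO / (V_other x P_other) = 1741.68 / 14.48"
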