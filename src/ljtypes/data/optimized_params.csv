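model,smirks,epsilon_kcal_mol,rmin_half_A
HCON,[#1:1]-[#6X4],0.017,1.27
HCON,[#1:1]-[#6X3],0.017,1.27
HCON,[#1:1]-[#7],0.017,1.27
HCON,[#1:1]-[#8],0.017,1.27
HCON,[#6:1],0.074,2.11
HCON,[#6X4:1],0.074,2.11
HCON,[#6X2:1],0.074,2.11
HCON,[#7X3:1],0.194,1.47
HCON,[#7:1],0.194,1.47
HCON,[#8:1],0.220,1.11
HCON,[#8X2H1+0:1],0.220,1.11
HCON,[#8X2H0+0:1],0.220,1.11
HCO3N,[#1:1]-[#6X4],0.034,1.42
HCO3N,[#1:1]-[#6X3],0.034,1.42
HCO3N,[#1:1]-[#7],0.034,1.42
HCO3N,[#1:1]-[#8],0.034,1.42
HCO3N,[#6:1],0.077,1.84
HCO3N,[#6X4:1],0.077,1.84
HCO3N,[#6X2:1],0.077,1.84
HCO3N,[#7X3:1],0.231,1.79
HCO3N,[#7:1],0.231,1.79
HCO3N,[#8:1],0.137,1.73
HCO3N,[#8X2H1+0:1],0.494,1.89
HCO3N,[#8X2H0+0:1],0.087,1.82
H2CON,[#1:1]-[#6X4],0.014,1.39
H2CON,[#1:1]-[#6X3],0.014,1.39
H2CON,[#1:1]-[#7],0.015,0.69
H2CON,[#1:1]-[#8],0.015,0.69
H2CON,[#6:1],0.081,2.06
H2CON,[#6X4:1],0.081,2.06
H2CON,[#6X2:1],0.081,2.06
H2CON,[#7X3:1],0.177,1.80
H2CON,[#7:1],0.177,1.80
H2CON,[#8:1],0.205,1.61
H2CON,[#8X2H1+0:1],0.205,1.61
H2CON,[#8X2H0+0:1],0.205,1.61
H2CO3N,[#1:1]-[#6X4],0.023,1.42
H2CO3N,[#1:1]-[#6X3],0.023,1.42
H2CO3N,[#1:1]-[#7],0.007,0.88
H2CO3N,[#1:1]-[#8],0.007,0.88
H2CO3N,[#6:1],0.078,1.96
H2CO3N,[#6X4:1],0.078,1.96
H2CO3N,[#6X2:1],0.078,1.96
H2CO3N,[#7X3:1],0.210,1.83
H2CO3N,[#7:1],0.210,1.83
H2CO3N,[#8:1],0.197,1.71
H2CO3N,[#8X2H1+0:1],0.218,1.60
H2CO3N,[#8X2H0+0:1],0.151,1.59
H2CO3Nreopt,[#1:1]-[#6X4],0.030,1.42
H2CO3Nreopt,[#1:1]-[#6X3],0.030,1.42
H2CO3Nreopt,[#1:1]-[#7],0.031,1.44
H2CO3Nreopt,[#1:1]-[#8],0.031,1.44
H2CO3Nreopt,[#6:1],0.078,1.87
H2CO3Nreopt,[#6X4:1],0.078,1.87
H2CO3Nreopt,[#6X2:1],0.078,1.87
H2CO3Nreopt,[#7X3:1],0.245,1.78
H2CO3Nreopt,[#7:1],0.245,1.78
H2CO3Nreopt,[#8:1],0.100,1.65
H2CO3Nreopt,[#8X2H1+0:1],0.533,1.87
H2CO3Nreopt,[#8X2H0+0:1],0.096,1.82
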