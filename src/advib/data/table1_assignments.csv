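freq_sixth_ml,freq_third_ml,assignment
3530,3465,nu_a(NH2)
3440,3375,nu_s(NH2)
3400,3280,nu_s(NH2)
3015,3070,nu_a(CH2)
2950,2980,nu_s(CH2)
1550,1540,nu_a(CO2);rho(CO2)
1510,1540,delta(NH2)
1410,1410,delta(CH2)
1365,1380,nu_s(CO2);delta(CO2);nu(CC)
,1300,omega(CH2);rho(NH2);tau(CN);delta(NCC)
1230,,t(CH2);omega(CH2)
1125,1155,rho(NH2);tau(CN);t(CH2);rho(CH2);omega(CH2)
1030,1085,omega(NH2);nu(CN)
970,950,nu(CN)
,910,rho(CH2);t(CH2);tau(CC);delta(NCC)
910,,rho(CH2);omega(NH2)
885,,nu(CC);delta(CO2)
700,750,omega(CO2);delta(NCC)
600,620,delta(CO2);omega(CO2)
500,560,tau(CN);tau(CC)
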