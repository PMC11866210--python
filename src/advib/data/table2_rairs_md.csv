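label,rairs,md,note
nu_a(CH2),2906,3070,
nu_s(CH2),2860,2980,
delta(CH2),1417,1410,delta(CH2) instead of nu_s(CO2)
nu_s(CO2),1417,1380,nu_s(CO2) but also delta(CO2); nu(CC)
omega(CH2),1332,1300,omega(CH2) but also rho(NH2); tau(CN); delta(NCC)
omega(NH2),1084,1085,omega(NH2); nu(CN)
nu(CN),969,950,nu(CN) instead of nu(CC)
rho(CH2),945,910,rho(CH2) but also t(CH2); tau(CC); delta(NCC)
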