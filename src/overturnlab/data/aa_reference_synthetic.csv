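amino_acid,mean_molpct,sd_molpct,factor_coef,carbon_atoms,in_di_set,source
Asp,8.0,1.5,0.05,4,1,synthetic stand-in reference composition
Glu,8.0,1.8,0.16,5,1,synthetic stand-in reference composition
Ser,11.0,1.6,-0.10,3,1,synthetic stand-in reference composition
Gly,22.0,3.5,-0.14,2,1,synthetic stand-in reference composition
Thr,6.0,1.1,-0.07,4,1,synthetic stand-in reference composition
Ala,13.0,2.0,0.02,3,1,synthetic stand-in reference composition
Arg,4.0,1.0,0.03,6,1,synthetic stand-in reference composition
Tyr,2.0,0.6,0.10,9,1,synthetic stand-in reference composition
Val,6.0,0.9,0.08,5,1,synthetic stand-in reference composition
Phe,3.0,0.7,0.13,9,1,synthetic stand-in reference composition
Ile,4.0,0.8,0.12,6,1,synthetic stand-in reference composition
Leu,6.0,1.2,0.13,6,1,synthetic stand-in reference composition
Met,1.0,0.4,0.07,5,1,synthetic stand-in reference composition
Lys,4.0,1.0,0.05,6,1,synthetic stand-in reference composition
His,2.0,0.6,0.02,6,1,synthetic stand-in reference composition
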