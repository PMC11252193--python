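site_id,lon,lat,pH,EC_uScm,TDS_mgL,Turbidity_NTU,Hardness_mgL,Na_mgL,K_mgL,Ca_mgL,Mg_mgL,Cl_mgL,SO4_mgL,HCO3_mgL,CO3_mgL,NO3_mgL,F_mgL
S1,68.2,31.0,7.2,450,300,2.0,180,15,2.0,48,12,18,40,170,0.0,1.0,0.3
S2,68.5,31.2,7.6,830,560,8.0,285,62,3.6,65,35,81,157,183,0.0,2.6,0.55
S3,69.0,31.4,7.9,1600,1100,12.0,420,160,5.0,95,55,260,240,240,2.0,6.0,0.9
S4,68.8,30.8,8.3,700,480,5.0,150,95,4.0,30,10,40,90,250,5.0,0.5,1.9
S5,69.3,31.1,7.1,1400,1000,15.0,480,70,3.0,150,70,120,380,200,0.0,9.5,0.2
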