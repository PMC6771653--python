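name,kc_ini,kc_mid,kc_end,l_ini,l_dev,l_mid,l_late,h_max,zr_ini,zr_max,p_tab,lai_max
wheat,0.30,1.15,0.25,30,30,40,30,1.0,0.20,1.20,0.55,5.0
maize,0.30,1.20,0.35,30,40,50,30,2.0,0.20,1.00,0.55,5.0
potato,0.50,1.15,0.75,25,30,45,30,0.6,0.15,0.60,0.35,4.0
grass,0.40,0.95,0.90,10,20,220,115,0.25,0.30,0.80,0.60,3.0
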