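scenario,max_EF_mV_per_mm,Q_stratum_corneum_W_per_m3,Q_epidermis_W_per_m3,Q_dermis_W_per_m3,Q_subcutis_W_per_m3
endogenous,96,8.90,6.77,4.75,0.28
geo1,40,8.05,2.14,2.34,0.12
geo2,40,8.50,1.54,1.82,0.07
geo3,13,7.57,1.10,1.16,0.04
geo4,22,6.02,0.39,0.64,0.03
geo5,20,1.48,0.36,0.13,0.02
geo5_air,16,,,,
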