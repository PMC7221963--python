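sample,id50_dpph,id50_dpph_sd,teac_dpph,id50_abts,id50_abts_sd,teac_abts,id50_tbars,id50_tbars_sd,teac_tbars,orac_te,orac_te_sd,raci_reported
TeaCEC,3.83,0.25,3.91,1.13,0.12,4.42,0.17,0.01,38.2,3.71,0.16,9.96
TeaTWF,66.52,0.25,0.22,5.28,0.72,0.95,3.14,0.61,2.04,2.72,0.16,-0.16
TeaSNC,15.37,0.51,0.97,2.26,0.32,2.20,0.28,0.01,22.8,3.57,0.63,5.62
TeaBNC,19.71,0.38,0.76,2.44,0.44,2.04,0.55,0.04,11.5,2.53,0.79,2.36
TeaMTC,31.15,0.25,0.48,3.35,0.53,1.49,1.79,0.12,3.57,2.72,0.32,0.32
TeaGNP,83.11,0.15,0.18,7.80,1.39,0.64,2.90,0.56,2.20,2.02,0.21,-0.44
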