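patient_id,wash_in_ratio_tsl_nat,wash_in_ratio_tsl_plt,wash_out_ratio_tsl_nat,wash_out_ratio_tsl_plt,fitted_max_nat,fitted_max_plt,fitted_max_tsl,fmcr_tsl_nat,fmcr_tsl_plt
1,3.27,1.94,0.63,0.58,1.00,2.16,4.22,4.22,1.95
2,4.17,3.40,-1.21,-0.79,1.00,1.16,3.01,3.01,2.60
3,1.57,1.70,-0.12,-0.12,0.98,1.07,1.46,1.49,1.36
4,5.91,1.41,1.55,0.83,1.01,5.36,10.61,10.45,1.98
6,4.21,2.64,-0.07,-0.04,0.98,1.41,3.26,3.32,2.30
7,2.12,1.85,1.24,0.74,0.95,1.44,3.27,3.46,2.27
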