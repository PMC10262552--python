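table,row,events_hd,n_hd,events_ld,n_ld,direction,rr,rr_lo,rr_hi,rd,rd_lo,rd_hi,p,note
2,response_14d,95,152,95,159,hd_ld,1.046,0.876,1.249,2.75,-8.08,13.58,0.619,
2,mortality_14d,36,152,44,159,hd_ld,0.856,0.585,1.252,-3.99,-13.57,5.74,0.421,
2,mortality_28d,47,152,60,159,hd_ld,0.819,0.601,1.118,-6.81,-17.12,3.73,0.206,
2,mortality_72h,15,152,15,159,hd_ld,1.046,0.530,2.066,0.43,-6.13,7.00,0.897,rr_ci_rounding_divergence
2,dead_day28,47,152,60,159,hd_ld,0.819,0.601,1.118,-6.81,-17.12,3.73,0.250,
2,alive_icu_day28,38,152,48,159,hd_ld,0.828,0.576,1.190,-5.19,-15.10,4.73,0.306,
2,alive_discharged_day28,25,152,15,159,hd_ld,1.743,0.956,3.175,7.01,-0.42,14.45,0.065,ci_rounding_divergence
2,alive_palliative_day28,4,152,3,159,hd_ld,1.395,0.163,3.151,0.74,-2.56,4.05,0.718,rr_ci_misprint
2,alive_hospitalized_day28,38,152,34,159,hd_ld,0.872,0.317,1.721,3.62,-5.76,13.00,0.506,rr_misprint
2,microbiological_cure,50,142,48,144,hd_ld,1.056,0.766,1.456,1.88,-9.03,12.74,0.738,
2,bacterial_persistence,80,142,80,144,hd_ld,1.014,0.826,1.246,0.78,-10.59,12.13,0.894,
2,superinfection,16,142,18,144,hd_ld,0.901,0.479,1.696,-1.23,-8.89,6.44,0.748,
3,within_window_dose2,80,148,42,157,hd_ld,2.021,1.499,2.723,27.30,16.37,37.35,<0.001,
3,above_window_dose2,13,148,8,157,hd_ld,1.724,0.736,4.040,3.69,-2.17,9.88,0.204,
3,within_window_dose7,81,127,51,131,hd_ld,1.638,1.274,2.106,24.85,12.68,35.99,<0.001,
3,above_window_dose7,15,127,4,131,hd_ld,3.868,1.319,11.340,8.76,2.35,15.77,0.007,
3,within_window_final,82,127,62,131,hd_ld,1.364,1.093,1.703,17.24,5.12,28.65,0.005,
3,above_window_final,12,127,4,131,hd_ld,3.095,1.025,9.343,6.40,0.37,13.00,0.033,rr_rounding_divergence
4,response_14d,12,25,14,28,hd_ld,0.960,0.553,1.666,-2.0,-27.0,23.4,0.884,
4,mortality_14d,6,25,9,28,hd_ld,0.747,0.309,1.802,-8.1,-30.5,15.9,0.511,
4,mortality_28d,10,25,15,28,hd_ld,0.747,0.413,1.348,-13.6,-37.3,12.6,0.323,
4,microbiological_cure,8,23,8,25,hd_ld,1.087,0.489,2.419,-2.8,22.5,-27.9,0.838,rd_sign_misprint
4,bacterial_persistence,15,23,13,25,hd_ld,1.254,0.776,2.028,13.2,-13.9,37.7,0.354,
4,superinfection,2,23,4,25,hd_ld,0.544,0.110,2.692,-7.3,-27.0,13.2,0.445,rr_rounded_pct
4,within_window_dose7,15,21,14,24,hd_ld,1.225,0.794,1.888,13.1,-14.4,37.6,0.360,rr_rounded_pct;rd_ci_rounding_divergence
4,above_window_dose7,3,21,0,24,hd_ld,,,,14.3,-2.4,34.6,0.055,rr_not_applicable
4,adverse_events,13,25,14,28,hd_ld,1.04,0.613,1.764,2.0,-23.4,27.0,0.884,
4,aki,4,25,6,28,hd_ld,0.747,0.238,2.345,-5.4,-25.9,16.3,0.614,
4,kdigo_stage1,2,4,3,6,hd_ld,1.000,0.282,3.544,0.0,46.9,46.9,1.000,rd_ci_sign_misprint
4,kdigo_stage2,1,4,2,6,hd_ld,0.750,0.098,5.768,-8.3,-50.3,42.5,1.000,rd_ci_rounding_divergence
4,kdigo_stage3,1,4,1,6,hd_ld,1.500,0.127,17.667,8.3,-36.3,55.3,1.000,
5,adverse_events,74,152,69,159,ld_hd,0.891,0.700,1.134,,,,0.350,
5,aki,30,152,32,159,ld_hd,1.020,0.653,1.592,,,,0.932,
5,kdigo_stage1,17,30,21,31,ld_hd,1.195,0.804,1.777,,,,0.372,
5,kdigo_stage2,10,30,8,31,ld_hd,0.774,0.354,1.693,,,,0.519,
5,kdigo_stage3,3,30,2,31,ld_hd,0.645,0.116,3.593,,,,0.614,
5,diarrhea,28,152,29,159,ld_hd,0.999,0.619,1.583,,,,0.967,rr_misprint
5,pigmentation,24,152,20,159,ld_hd,0.797,0.460,1.381,,,,0.417,
5,superinfection,17,152,20,159,ld_hd,1.125,0.613,2.064,,,,0.704,
5,coagulation_abnormalities,10,152,9,159,ld_hd,0.860,0.359,2.059,,,,0.735,
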