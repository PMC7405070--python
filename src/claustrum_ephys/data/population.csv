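key,IN_mean,IN_sem,IN_median,IN_mad,PN_mean,PN_sem,PN_median,PN_mad
rmp,-63.3,0.45,-63.7,4.00,-71.9,0.26,-72.0,2.28
rm,389,19.9,326,138,246,9.22,227,68.8
ct,87.4,5.95,60.0,40.0,136,5.84,120,40.0
adp_probability,0.13,0.03,0.00,0.00,0.62,0.04,1.00,0.00
adp_mean,0.13,0.04,0.00,0.00,0.87,0.08,0.54,0.54
max_init_adapt_change,1.51,0.08,1.36,0.66,1.68,0.09,1.41,0.77
adapt_change_rel_ct,2.01,0.13,1.33,0.33,1.60,0.04,1.43,0.24
init_adapt_change_v2,1.05,0.07,0.71,0.23,1.49,0.08,1.17,0.57
adapt_change_rel_ct_v2,2.42,0.13,2.00,0.70,1.65,0.04,1.50,0.25
ct_ahp_amp,-19.3,0.45,-19.1,4.26,-12.5,0.27,-12.0,2.58
ct_ahp_lat,6.25,0.88,3.60,1.10,42.8,4.26,11.3,7.43
ct_max_rise,187,4.61,180,39.1,194,3.08,192,30.5
ct_max_decay,-74.0,3.14,-61.7,19.5,-38.7,0.51,-37.5,4.69
ct_half_width,1.26,0.04,1.22,0.37,1.84,0.03,1.78,0.19
ct_ap_thresh,-34.3,0.35,-34.5,2.98,-33.8,0.22,-34.0,2.02
ct_ap_amp,68.9,0.66,69.7,5.58,75.6,0.38,76.2,3.16
x2_n_ap,33.5,2.15,22.0,11.0,15.5,0.38,15.0,4.0
x2_latency,25.0,1.74,18.3,10.6,21.9,0.67,20.6,4.85
x2_ahp_amp,-15.8,0.41,-15.5,3.59,-5.98,0.33,-5.63,2.80
x2_ahp_lat,3.35,0.14,3.10,0.91,4.03,0.05,4.04,0.44
x2_max_rise,192,4.93,185,37.5,195,3.44,187,31.8
x2_max_decay,-75.6,2.99,-62.5,18.8,-43.2,0.59,-42.2,4.69
x2_half_width,1.21,0.03,1.17,0.31,1.69,0.02,1.67,0.14
x2_ap_thresh,-36.4,0.39,-36.2,3.02,-35.9,0.26,-36.1,2.24
x2_ap_amp,69.7,0.57,70.3,4.53,74.4,0.35,74.9,2.85
x2_amp_ratio_1_2,1.08,0.01,1.06,0.03,1.33,0.01,1.31,0.13
x2_amp_ratio_2_3,1.02,0.00,1.02,0.01,0.95,0.01,0.96,0.07
x2_amp_ratio_1_last,1.18,0.01,1.14,0.06,1.29,0.02,1.22,0.10
x2_init_freq,51.1,2.75,39.0,19.9,67.4,2.25,68.1,24.1
x2_adaptation,17.1,1.10,14.7,9.00,54.3,2.24,55.9,23.8
x2_isi_ratio,0.67,0.03,0.67,0.13,0.24,0.01,0.18,0.06
x2_mean_first2_isi,32.9,1.82,29.3,14.7,29.9,1.34,26.9,9.19
x2_sd_first2_isi,5.14,0.62,2.32,1.62,15.0,1.06,9.48,4.90
x2_delta_isi_1_2,3.09,1.02,2.61,2.01,21.2,1.50,13.4,6.93
x2_delta_f_1_2,-6.42,0.71,-6.05,4.72,-34.1,1.57,-32.8,17.5
x2_cv2_all,0.12,0.01,0.07,0.03,0.21,0.01,0.18,0.07
x2_cv2_excl1,0.11,0.01,0.06,0.03,0.16,0.01,0.12,0.05
x2_cv2_excl2,0.11,0.01,0.06,0.03,0.14,0.01,0.10,0.04
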