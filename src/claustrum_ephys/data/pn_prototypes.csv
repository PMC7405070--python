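key,PN1_median,PN1_mad,PN2_median,PN2_mad,PN3_median,PN3_mad,PN4_median,PN4_mad,PN5_median,PN5_mad,outlierVIP_value
rmp,-73.9,2.01,-74.8,1.59,-71.5,1.92,-70.5,1.44,-68.7,1.44,-64.9
rm,248,55.4,151,38.4,219,43.0,238,59.6,399,82.7,755
ct,100,40.0,220,60.0,120,40.0,100,20.0,40.0,15.0,30.0
adp_probability,0.00,0.00,0.00,0.00,1.00,0.00,1.00,0.00,1.00,0.00,1.00
adp_mean,0.00,0.00,0.00,0.00,1.46,0.70,1.12,0.72,1.42,0.89,0.99
max_init_adapt_change,0.44,0.08,0.99,0.35,3.18,0.48,1.47,0.36,1.05,0.26,5.67
adapt_change_rel_ct,1.95,0.45,1.28,0.09,1.25,0.10,1.50,0.17,2.29,0.29,3.33
init_adapt_change_v2,0.44,0.08,0.91,0.27,2.74,0.67,1.42,0.40,1.05,0.26,5.67
adapt_change_rel_ct_v2,1.95,0.45,1.29,0.08,1.33,0.13,1.50,0.17,2.33,0.33,3.33
ct_ahp_amp,-14.8,2.17,-14.5,1.99,-10.2,1.59,-10.8,2.12,-11.7,2.15,-7.78
ct_ahp_lat,9.22,2.77,6.57,2.27,56.5,51.8,63.6,36.7,8.75,4.33,4.12
ct_max_rise,222,25.0,191,30.5,215,22.7,167,14.1,164,15.2,172
ct_max_decay,-39.1,4.69,-38.3,3.91,-43.8,3.13,-34.4,3.13,-33.6,3.91,-48.4
ct_half_width,1.94,0.16,1.76,0.14,1.57,0.13,1.93,0.17,2.00,0.23,1.61
ct_ap_thresh,-36.1,1.98,-32.1,1.95,-34.8,1.11,-33.1,2.18,-33.1,1.69,-39.8
ct_ap_amp,81.6,2.82,71.5,3.08,77.2,1.68,73.9,3.02,74.2,3.09,76.7
x2_n_ap,20.0,2.00,14.5,2.50,17.5,2.50,13.0,3.00,9.50,2.50,8.00
x2_latency,17.8,3.02,15.2,2.58,21.3,3.44,24.9,3.26,42.0,5.71,17.0
x2_ahp_amp,-11.3,2.59,-6.15,2.06,-2.84,1.40,-3.57,1.99,-8.56,1.74,-2.98
x2_ahp_lat,4.34,0.32,4.06,0.32,3.39,0.28,4.14,0.36,4.53,0.25,3.86
x2_max_rise,224,24.2,190,35.9,205,30.5,166,18.8,166,16.4,169
x2_max_decay,-44.5,5.47,-43.0,4.69,-48.4,4.69,-37.5,3.13,-37.5,1.56,-46.9
x2_half_width,1.64,0.09,1.77,0.17,1.46,0.11,1.77,0.16,1.75,0.14,1.64
x2_ap_thresh,-37.7,2.47,-36.7,2.96,-36.7,1.40,-34.7,2.24,-34.5,0.99,-41.7
x2_ap_amp,78.7,2.54,73.9,2.64,75.9,2.16,72.2,2.65,72.7,2.01,77.3
x2_amp_ratio_1_2,1.14,0.03,1.30,0.09,1.41,0.10,1.40,0.11,1.18,0.05,1.15
x2_amp_ratio_2_3,1.05,0.02,0.99,0.04,0.93,0.07,0.87,0.05,0.95,0.02,1.01
x2_amp_ratio_1_last,1.56,0.20,1.32,0.12,1.16,0.07,1.16,0.05,1.11,0.04,1.18
x2_init_freq,34.7,3.25,72.7,11.2,100,13.0,70.2,8.25,29.0,10.19,16.0
x2_adaptation,18.2,3.50,59.1,13.2,86.0,11.9,58.3,9.69,18.6,8.62,2.49
x2_isi_ratio,0.50,0.07,0.17,0.06,0.14,0.03,0.15,0.04,0.31,0.05,0.46
x2_mean_first2_isi,33.8,3.89,19.7,3.59,16.0,4.54,29.3,6.58,50.7,14.6,133
x2_sd_first2_isi,5.88,1.87,7.73,2.61,7.95,4.07,21.5,7.38,22.6,5.20,99.4
x2_delta_isi_1_2,8.32,2.64,10.9,3.69,11.2,5.76,30.5,10.4,31.9,7.36,141
x2_delta_f_1_2,-8.74,2.24,-30.6,5.09,-56.0,12.4,-43.0,10.5,-13.4,6.19,-11.1
x2_cv2_all,0.07,0.01,0.21,0.09,0.16,0.04,0.23,0.07,0.27,0.09,0.86
x2_cv2_excl1,0.06,0.01,0.18,0.10,0.11,0.03,0.16,0.04,0.21,0.09,0.82
x2_cv2_excl2,0.05,0.01,0.15,0.09,0.08,0.02,0.13,0.05,0.18,0.08,0.92
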