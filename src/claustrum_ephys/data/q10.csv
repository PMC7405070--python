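key,mean_q10,sem
ct,1.67,0.24
rmp,1.04,0.02
rm,0.81,0.09
x2_rise_half_width_ratio,7.75,0.93
ct_rise_half_width_ratio,7.33,0.73
max_rise_half_width_ratio,6.96,1.01
x2_adaptation,3.28,0.68
x2_max_decay,3.27,0.22
max_max_decay,3.15,0.30
ct_max_decay,2.92,0.18
x2_max_rise,1.80,0.14
ct_max_rise,1.75,0.10
max_max_rise,1.67,0.16
ct_rise_decay_ratio,0.62,0.04
x2_rise_decay_ratio,0.56,0.03
max_rise_decay_ratio,0.54,0.03
max_half_width,0.27,0.02
ct_half_width,0.26,0.02
x2_half_width,0.26,0.02
max_n_ap,5.26,1.51
init_adapt_change_v2,5.11,0.99
max_delta_f_1_2,4.68,1.63
x2_init_freq,4.60,1.07
x2_delta_f_1_2,4.09,0.75
max_adaptation,4.08,1.32
x2_n_ap,4.05,0.74
max_init_adapt_change,3.29,0.51
max_init_freq,3.28,0.55
x2_delta_isi_1_2,1.52,0.44
x2_sd_first2_isi,1.42,0.42
max_isi_ratio,1.21,0.25
x2_isi_ratio,1.15,0.15
adapt_change_rel_ct,1.12,0.14
adapt_change_rel_ct_v2,1.04,0.15
x2_mean_first2_isi,0.61,0.15
max_delta_isi_1_2,0.53,0.30
max_mean_first2_isi,0.41,0.10
max_sd_first2_isi,0.20,0.09
x2_thresh_amp_ratio,1.72,0.11
ct_thresh_amp_ratio,1.69,0.10
max_thresh_amp_ratio,1.67,0.11
ct_ahp_amp,1.18,0.19
max_ahp_amp,1.09,0.33
ct_ap_thresh,1.05,0.03
max_ap_thresh,1.03,0.05
x2_ap_thresh,1.00,0.03
x2_amp_ratio_2_3,0.98,0.03
max_amp_ratio_2_3,0.90,0.04
x2_ahp_amp,0.85,0.17
x2_amp_ratio_1_last,0.76,0.03
max_amp_ratio_1_last,0.75,0.06
max_amp_ratio_1_2,0.73,0.03
x2_amp_ratio_1_2,0.69,0.03
ct_ap_amp,0.64,0.03
max_ap_amp,0.64,0.04
x2_ap_amp,0.62,0.03
adp_mean,0.87,0.29
adp_probability,0.84,0.08
ct_ahp_lat,0.67,0.15
x2_cv2_all,0.66,0.10
x2_latency,0.64,0.12
x2_cv2_excl2,0.62,0.08
x2_cv2_excl1,0.61,0.07
max_cv2_excl2,0.60,0.17
max_cv2_excl1,0.59,0.16
max_latency,0.51,0.08
max_cv2_all,0.51,0.14
x2_ahp_lat,0.26,0.02
max_ahp_lat,0.25,0.02
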