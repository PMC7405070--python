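key,PV_mean,PV_sem,PV_median,PV_mad,SST_mean,SST_sem,SST_median,SST_mad,VIP_mean,VIP_sem,VIP_median,VIP_mad
rmp,-66.4,1.20,-67.2,2.30,-62.2,1.10,-63.0,4.10,-59.8,0.90,-59.8,2.50
rm,159,10.5,157,29.3,414,31.0,389,108,653,38.7,616,148
ct,165,11.0,160,40.0,54.3,6.40,40.0,20.0,24.0,1.90,20.0,0.00
ct_ahp_amp,-22.8,0.90,-22.4,2.00,-21.2,1.00,-20.0,3.50,-14.3,0.70,-13.4,2.40
ct_ahp_lat,1.88,0.09,1.80,0.28,4.91,1.11,3.58,0.46,4.30,0.17,4.17,0.56
ct_max_rise,243,11.5,263,17.2,180,7.10,184,28.1,161,6.60,154,32.0
ct_max_decay,-127,6.40,-134,21.9,-65.0,2.70,-66.4,9.90,-47.6,1.70,-45.3,4.70
ct_half_width,0.71,0.03,0.67,0.09,1.20,0.04,1.19,0.09,1.60,0.04,1.59,0.12
ct_ap_thresh,-37.5,1.20,-37.2,2.60,-33.4,0.70,-34.2,2.80,-33.3,0.70,-33.4,2.30
ct_ap_amp,67.6,1.70,68.3,4.00,69.5,1.60,70.6,6.60,72.4,1.00,72.4,4.10
ct_rise_decay_ratio,1.92,0.04,1.86,0.11,2.83,0.12,2.79,0.41,3.42,0.12,3.25,0.36
ct_thresh_amp_ratio,-0.55,0.01,-0.56,0.03,-0.48,0.01,-0.49,0.02,-0.46,0.01,-0.47,0.03
ct_rise_half_width_ratio,362,27.7,395,90.8,158,9.70,162,29.3,105,6.80,99.2,23.0
x2_n_ap,67.3,4.40,71.0,13.0,22.5,2.30,20.5,7.00,14.9,1.00,14.5,3.50
x2_latency,7.70,0.80,7.70,1.40,36.4,4.60,31.3,14.0,37.3,4.40,33.4,14.0
x2_ahp_amp,-17.0,0.80,-16.7,2.60,-18.6,0.90,-17.9,3.80,-13.4,0.80,-13.3,2.30
x2_ahp_lat,1.80,0.07,1.78,0.24,3.33,0.16,3.10,0.44,4.00,0.12,4.03,0.36
x2_max_rise,253,10.7,270,30.5,182,8.60,187,21.1,160,6.00,159,27.3
x2_max_decay,-125,5.20,-130,12.8,-67.0,2.90,-67.9,7.10,-49.2,1.50,-49.4,4.70
x2_half_width,0.77,0.03,0.73,0.10,1.16,0.04,1.13,0.10,1.55,0.04,1.53,0.12
x2_ap_thresh,-41.6,1.00,-43.1,2.50,-34.7,0.70,-35.2,1.50,-34.3,0.70,-34.4,1.90
x2_ap_amp,70.3,1.40,70.9,2.00,69.6,1.50,70.6,5.50,72.3,1.00,72.1,3.30
x2_rise_decay_ratio,2.00,0.00,2.00,0.10,2.80,0.10,2.70,0.30,3.30,0.10,3.20,0.30
x2_thresh_amp_ratio,-0.59,0.01,-0.61,0.02,-0.50,0.01,-0.51,0.02,-0.47,0.01,-0.48,0.04
x2_rise_half_width_ratio,345,23.0,372,63.5,168,13.2,166,43.1,108,6.20,103,21.9
x2_amp_ratio_1_2,1.05,0.01,1.05,0.02,1.06,0.01,1.04,0.02,1.11,0.01,1.09,0.05
x2_amp_ratio_2_3,1.01,0.00,1.01,0.01,1.02,0.00,1.02,0.01,1.02,0.01,1.01,0.01
x2_amp_ratio_1_last,1.13,0.02,1.13,0.05,1.15,0.02,1.12,0.06,1.26,0.04,1.19,0.09
x2_init_freq,92.7,5.30,86.0,18.1,33.0,3.20,30.2,9.00,32.5,2.30,31.4,8.70
x2_adaptation,25.4,2.90,24.0,9.30,10.9,1.70,10.4,4.30,17.7,2.70,19.2,9.70
x2_isi_ratio,0.73,0.03,0.74,0.05,0.69,0.03,0.70,0.09,0.49,0.06,0.44,0.19
x2_mean_first2_isi,12.2,0.80,11.9,2.00,43.7,5.10,34.9,10.7,38.2,2.50,34.3,6.80
x2_sd_first2_isi,1.00,0.10,1.00,0.50,4.80,1.10,3.00,1.70,7.60,1.30,5.50,4.00
x2_delta_isi_1_2,1.50,0.20,1.40,0.70,6.80,1.60,4.30,2.40,3.90,2.60,6.40,6.10
x2_delta_f_1_2,-10.6,1.20,-10.4,3.70,-5.00,1.10,-4.00,2.10,-4.80,2.00,-6.70,5.30
x2_cv2_all,0.05,0.02,0.03,0.01,0.08,0.01,0.06,0.02,0.23,0.03,0.21,0.11
x2_cv2_excl1,0.05,0.02,0.03,0.01,0.07,0.01,0.05,0.02,0.23,0.03,0.16,0.10
x2_cv2_excl2,0.05,0.02,0.03,0.01,0.07,0.01,0.04,0.02,0.23,0.03,0.17,0.11
max_n_ap,93.4,5.20,97.0,14.0,37.3,2.30,37.0,9.50,23.4,1.50,22.5,6.50
max_latency,4.00,0.40,3.10,0.80,11.2,0.90,11.6,3.50,21.7,4.10,13.4,4.70
max_ahp_amp,-12.7,0.80,-13.4,3.40,-15.4,0.90,-15.3,3.60,-11.4,0.90,-11.4,3.00
max_ahp_lat,1.77,0.07,1.73,0.29,2.90,0.12,2.78,0.33,3.75,0.12,3.73,0.41
max_max_rise,269,14.6,277,25.4,178,10.1,178,26.1,158,6.70,152,28.9
max_max_decay,-127,6.80,-127,19.5,-66.6,3.30,-66.4,7.00,-48.9,1.90,-46.9,3.90
max_half_width,0.84,0.03,0.81,0.09,1.14,0.04,1.16,0.13,1.54,0.04,1.51,0.11
max_ap_thresh,-43.4,1.40,-44.3,4.30,-34.7,0.80,-35.1,1.60,-33.8,0.60,-34.0,2.00
max_ap_amp,70.0,1.40,70.8,2.40,67.5,1.40,67.7,4.80,70.7,0.80,70.7,3.10
max_rise_decay_ratio,2.12,0.04,2.06,0.11,2.68,0.07,2.71,0.27,3.25,0.09,3.23,0.32
max_thresh_amp_ratio,-0.62,0.01,-0.64,0.02,-0.51,0.01,-0.51,0.02,-0.48,0.01,-0.48,0.04
max_rise_half_width_ratio,335,26.5,335,64.8,166,15.1,158,38.2,107,7.20,100,21.0
max_amp_ratio_1_2,1.11,0.00,1.11,0.02,1.14,0.02,1.12,0.04,1.22,0.02,1.22,0.12
max_amp_ratio_2_3,1.04,0.00,1.04,0.01,1.04,0.01,1.03,0.01,1.05,0.01,1.05,0.03
max_amp_ratio_1_last,1.37,0.03,1.35,0.10,1.42,0.03,1.41,0.09,1.48,0.04,1.48,0.18
max_init_freq,139,6.30,140,17.1,71.7,4.20,71.0,15.8,58.1,4.70,57.9,24.5
max_adaptation,50.2,2.80,48.9,8.80,38.3,3.20,37.0,10.9,36.5,4.50,38.1,19.5
max_isi_ratio,0.60,0.00,0.70,0.00,0.50,0.00,0.50,0.10,0.50,0.10,0.30,0.10
max_mean_first2_isi,8.10,0.50,7.70,0.90,16.6,1.10,15.2,3.20,26.3,2.80,21.4,7.70
max_sd_first2_isi,0.70,0.10,0.60,0.10,1.70,0.20,1.50,0.70,6.00,1.50,3.60,1.70
max_delta_isi_1_2,1.00,0.10,0.90,0.20,2.10,0.30,2.00,0.90,5.70,2.40,4.30,2.70
max_delta_f_1_2,-15.6,1.10,-16.2,3.60,-9.80,1.30,-9.20,3.60,-14.9,2.80,-16.2,6.70
max_cv2_all,0.03,0.00,0.03,0.01,0.07,0.01,0.06,0.02,0.18,0.03,0.11,0.05
max_cv2_excl1,0.03,0.00,0.02,0.01,0.07,0.01,0.06,0.02,0.17,0.03,0.10,0.05
max_cv2_excl2,0.03,0.00,0.02,0.01,0.07,0.01,0.05,0.02,0.17,0.03,0.10,0.05
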