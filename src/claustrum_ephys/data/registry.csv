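key,label_38,label_63,unit,level,lognormal,negative
rmp,RMP (mV),RMP (mV),mV,global,0,1
rm,Rm (MΩ),Rm (MΩ),MΩ,global,1,0
ct,ct,current threshold (ct: pA),pA,global,1,0
adp_probability,ADP probability,,1,ct,0,0
adp_mean,Mean ADP value (mV),,mV,ct,0,0
max_init_adapt_change,Max initial adaptation change (Hz/pA),,Hz/pA,global,0,0
adapt_change_rel_ct,Max adaptation change relative to ct,,1,global,0,0
init_adapt_change_v2,Initial adaptation change (2) (Hz/pA),,Hz/pA,global,0,0
adapt_change_rel_ct_v2,Max adaptation change relative to ct (2),,1,global,0,0
ct_ahp_amp,AHP amplitude (mV),ct: AHP amplitude (mV),mV,ct,0,1
ct_ahp_lat,AHP latency (ms),ct: AHP latency (ms),ms,ct,1,0
ct_max_rise,Max AP rise (mV/ms),ct: max AP rise (mV/ms),mV/ms,ct,0,0
ct_max_decay,Max AP decay (mV/ms),ct: max AP decay (mV/ms),mV/ms,ct,0,1
ct_half_width,AP half-width (ms),ct: AP half-width (ms),ms,ct,0,0
ct_ap_thresh,AP threshold (mV),ct: AP threshold (mV),mV,ct,0,1
ct_ap_amp,AP amplitude (mV),ct: AP amplitude (mV),mV,ct,0,0
ct_rise_decay_ratio,,ct: AP rise/decay ratio,1,ct,0,0
ct_thresh_amp_ratio,,ct: AP threshold/AP amp.,1,ct,0,1
ct_rise_half_width_ratio,,ct: AP rise/AP half-width,mV/ms^2,ct,0,0
x2_n_ap,2xct: number of AP,2xct: # AP,count,2xct,0,0
x2_latency,2xct: latency to first AP,2xct: latency to first AP (ms),ms,2xct,1,0
x2_ahp_amp,2xct: AHP amplitude (mV),2xct: AHP amplitude (mV),mV,2xct,0,1
x2_ahp_lat,2xct: AHP latency (ms),2xct: AHP latency,ms,2xct,1,0
x2_max_rise,2xct: max AP rise (mV/ms),2xct: max AP rise (mV/ms),mV/ms,2xct,0,0
x2_max_decay,2xct: max AP decay (mV/ms),2xct: max AP decay (mV/ms),mV/ms,2xct,0,1
x2_half_width,2xct: AP half-width (ms),2xct: AP half-width (ms),ms,2xct,0,0
x2_ap_thresh,2xct: AP threshold (mV),2xct: AP threshold (mV),mV,2xct,0,1
x2_ap_amp,2xct: AP amplitude (mV),2xct: AP amplitude (mV),mV,2xct,0,0
x2_rise_decay_ratio,,2xct: AP rise/decay ratio,1,2xct,0,0
x2_thresh_amp_ratio,,2xct: AP thresh/AP ampl,1,2xct,0,1
x2_rise_half_width_ratio,,2xct: AP rise/AP half-width,mV/ms^2,2xct,0,0
x2_amp_ratio_1_2,2xct: 1st/2nd AP ratio,2xct: amp 1st/2nd AP,1,2xct,0,0
x2_amp_ratio_2_3,2xct: 2nd/3rd AP ratio,2xct: amp 2nd/3rd AP,1,2xct,0,0
x2_amp_ratio_1_last,2xct: 1st/last AP ratio,2xct: amp 1st/last AP,1,2xct,0,0
x2_init_freq,2xct: initial instant frequency,2xct: initial instant frequency (Hz),Hz,2xct,0,0
x2_adaptation,2xct: max adaptation (Hz),2xct: adaptation (Hz),Hz,2xct,0,0
x2_isi_ratio,2xct: ISI ratio,2xct: ISI ratio,1,2xct,0,0
x2_mean_first2_isi,2xct: mean of first 2 ISI (ms),2xct: mean of first 2 ISI (ms),ms,2xct,1,0
x2_sd_first2_isi,2xct: SD of first 2 ISI (ms),2xct: SD of first 2 ISI (ms),ms,2xct,1,0
x2_delta_isi_1_2,2xct: change of ISI duration from 1st to 2nd AP (ms),2xct: change of ISI duration from 1st to 2nd AP (ms),ms,2xct,0,0
x2_delta_f_1_2,2xct: change of instant frequency from 1st to 2nd AP pair (Hz),2xct: change of instant frequency from 1st to 2nd AP pair (Hz),Hz,2xct,0,1
x2_cv2_all,2xct: Cv2:all,2xct: Cv2:all,1,2xct,1,0
x2_cv2_excl1,2xct: Cv2-1st AP,2xct: Cv2-1st AP,1,2xct,1,0
x2_cv2_excl2,2xct: Cv2-1st/2nd AP,2xct: Cv2-1st/2nd AP,1,2xct,1,0
max_n_ap,,Max AP: # AP,count,maxap,0,0
max_latency,,Max AP: latency to first AP (ms),ms,maxap,1,0
max_ahp_amp,,Max AP: AHP amplitude (mV),mV,maxap,0,1
max_ahp_lat,,Max AP: AHP latency (ms),ms,maxap,1,0
max_max_rise,,Max AP: max AP rise (mV/ms),mV/ms,maxap,0,0
max_max_decay,,Max AP: max AP decay (mV/ms),mV/ms,maxap,0,1
max_half_width,,Max AP: AP half-width (ms),ms,maxap,0,0
max_ap_thresh,,Max AP: AP threshold (mV),mV,maxap,0,1
max_ap_amp,,Max AP: AP amplitude (mV),mV,maxap,0,0
max_rise_decay_ratio,,Max AP: AP rise/decay ratio,1,maxap,0,0
max_thresh_amp_ratio,,Max AP: AP thresh/AP amp,1,maxap,0,1
max_rise_half_width_ratio,,Max AP: AP rise/AP half-width,mV/ms^2,maxap,0,0
max_amp_ratio_1_2,,Max AP: amp 1st/2nd AP,1,maxap,0,0
max_amp_ratio_2_3,,Max AP: amp 2nd/3rd AP,1,maxap,0,0
max_amp_ratio_1_last,,Max AP: amp 1st/last AP,1,maxap,0,0
max_init_freq,,Max AP: initial instant frequency (Hz),Hz,maxap,0,0
max_adaptation,,Max AP: adaptation (Hz),Hz,maxap,0,0
max_isi_ratio,,Max AP: ISI ratio,1,maxap,0,0
max_mean_first2_isi,,Max AP: mean of first 2 ISI (ms),ms,maxap,1,0
max_sd_first2_isi,,Max AP: SD of first 2 ISI (ms),ms,maxap,1,0
max_delta_isi_1_2,,Max AP: change of ISI duration from 1st to 2nd AP (ms),ms,maxap,0,0
max_delta_f_1_2,,Max AP: change of instant frequency from 1st to 2nd AP pair (Hz),Hz,maxap,0,1
max_cv2_all,,Max AP: Cv2:all,1,maxap,1,0
max_cv2_excl1,,Max AP: Cv2-1st AP,1,maxap,1,0
max_cv2_excl2,,Max AP: Cv2-1st/2nd AP,1,maxap,1,0
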