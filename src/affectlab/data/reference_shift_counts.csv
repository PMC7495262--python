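group,increased_theta_beta,decreased_alpha,increased_hr,increased_eda
total,6,5,2,9
student,2,1,0,4
neurosurgeon,3,1,3,4
postgraduate,2,3,0,2
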