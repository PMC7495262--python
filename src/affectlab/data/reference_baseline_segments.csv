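segment,alpha_amp,theta_beta,hr,eda
1,4.886,3.198,86,0.227
2,5.259,2.235,90,0.209
3,4.883,3.047,88,0.203
4,4.921,3.584,89,0.203
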