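group,metric,condition,mean,sd
student,theta_beta,VP,3.49,0.82
student,theta_beta,MR,3.23,0.94
student,alpha_amp,VP,7.77,1.62
student,alpha_amp,MR,8.42,2.56
student,hr,VP,87,13
student,hr,MR,86,12
student,eda,VP,1.198,1.467
student,eda,MR,4.097,2.79
neurosurgeon,theta_beta,VP,2.59,0.96
neurosurgeon,theta_beta,MR,2.90,1.78
neurosurgeon,alpha_amp,VP,7.03,2.19
neurosurgeon,alpha_amp,MR,7.15,1.86
neurosurgeon,hr,VP,81,7
neurosurgeon,hr,MR,83,7
neurosurgeon,eda,VP,1.890,2.269
neurosurgeon,eda,MR,5.407,5.391
postgraduate,theta_beta,VP,2.33,0.26
postgraduate,theta_beta,MR,2.56,0.62
postgraduate,alpha_amp,VP,11.84,6.15
postgraduate,alpha_amp,MR,9.55,3.12
postgraduate,hr,VP,81,7
postgraduate,hr,MR,77,6
postgraduate,eda,VP,0.739,0.509
postgraduate,eda,MR,2.498,1.72
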