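participant_id,group,theta_beta_vp,theta_beta_mr,alpha_amp_vp,alpha_amp_mr,hr_vp,hr_mr,eda_vp,eda_mr
student-1,student,4.315,4.417,8.024,8.540,97,96,3.733,6.479
student-2,student,2.734,1.788,10.228,12.443,92,92,0.525,2.438
student-3,student,4.306,3.425,5.794,5.529,66,65,0.268,0.382
student-4,student,2.611,3.284,7.040,7.157,96,90,0.265,7.090
neurosurgeon-1,neurosurgeon,3.016,3.131,7.033,7.146,87,95,0.215,3.475
neurosurgeon-2,neurosurgeon,1.438,1.598,6.023,6.223,88,82,5.788,14.539
neurosurgeon-3,neurosurgeon,1.986,1.679,6.396,8.072,75,76,1.019,3.076
neurosurgeon-4,neurosurgeon,3.935,5.420,10.725,9.606,73,79,0.538,0.540
postgraduate-1,postgraduate,2.439,2.532,7.831,7.801,75,70,0.371,0.307
postgraduate-2,postgraduate,2.580,3.331,20.523,13.933,90,84,0.387,4.516
postgraduate-3,postgraduate,1.971,1.823,7.163,6.926,77,79,1.459,2.671
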