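female_class,male_class,cycle,eclosion_rate,se,n_pupae
w,w,1,0.82,0.08,67
w,w,2,0.89,0.05,61
w,a,1,0.83,0.09,45
w,a,2,0.93,0.06,38
a,a,1,0.60,0.18,34
a,a,2,0.52,0.24,27
a,w,1,0.17,0.28,4
a,w,2,,,0
m,m,1,0.88,0.07,33
m,m,2,0.75,0.13,25
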