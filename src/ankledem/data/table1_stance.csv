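percent_stance,angle_deg,force_ml_N,force_pa_N,force_si_N
12,-0.57,13.64,21.7,72.5
20,5.37,65.25,143.87,1071
55,10.7,106.86,-22.14,2047
69,12.92,158.82,-35.45,3209.7
78,16.31,159.94,-52.52,4078.26
87,17.1,89.32,-33.88,3714.94
92,15.1,28.2,-29.46,2741.62
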