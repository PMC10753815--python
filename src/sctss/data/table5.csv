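class,patient_number,predicted_number,tp,sensitivity_pct,precision_pct,f_value
CE,51,51,49,96,96,0.96
CE-PFO,7,0,0,0,,
LAS,29,35,29,100,83,0.91
SVO,25,32,25,100,78,0.88
BAD,28,31,27,96,87,0.92
Aorto,40,49,30,75,61,0.67
Tro,9,7,4,44,57,0.50
Dissec,15,3,1,7,33,0.11
Other,27,23,12,44,52,0.48
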