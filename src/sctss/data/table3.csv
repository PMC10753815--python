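class,patient_number,predicted_number,tp,sensitivity_pct,precision_pct,f_value
CE,51,51,49,96,96,0.96
LAS,29,35,29,100,83,0.91
SVO/BAD,53,63,52,98,83,0.90
Tro,9,7,4,44,57,0.50
ESUS+D,89,75,71,80,95,0.87
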