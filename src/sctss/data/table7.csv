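class,patient_number,predicted_number,tp,sensitivity_pct,precision_pct,f_value
CE,52,46,44,85,96,0.90
LAS,25,24,22,88,92,0.90
SVO/BAD,33,38,30,91,79,0.85
Tro,9,7,6,67,86,0.75
ESUS+D,32,36,28,88,78,0.82
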