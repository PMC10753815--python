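true,CE,LAS,SVO/BAD,Tro,ESUS+D
CE,49,0,1,1,0
LAS,0,29,0,0,0
SVO/BAD,0,0,52,0,1
Tro,0,1,1,4,3
ESUS+D,2,5,9,2,71
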