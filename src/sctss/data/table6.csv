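true,CE,LAS,SVO/BAD,Tro,ESUS+D
CE,44,2,4,0,2
LAS,0,22,2,0,1
SVO/BAD,0,0,30,0,2
Tro,0,0,0,6,3
ESUS+D,2,0,2,0,28
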