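true,CE,CE-PFO,LAS,SVO,BAD,Aorto,Tro,Dissec,Other
CE,49,0,0,0,1,0,1,0,0
CE-PFO,0,0,0,0,1,1,0,0,5
LAS,0,0,29,0,0,0,0,0,0
SVO,0,0,0,25,0,0,0,0,0
BAD,0,0,0,0,27,1,0,0,0
Aorto,0,0,2,1,0,30,2,0,5
Tro,0,0,1,0,1,3,4,0,0
Dissec,2,0,2,4,1,4,0,1,1
Other,0,0,1,2,0,10,0,2,12
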