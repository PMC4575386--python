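label,mass,copper_sulfate,acridine,bnf
A,4562,,down**,up*
B,4576,,,up*
C,4633,up**,down**,up*
D,4647,,down*,up*
E,4885,,,down**
F,4902,,up**,down**
G,5655,up*,,
H,6275,,,up*
I,6731,up**,,
J,10540,up*,,
K,11295,up**,up*,down*
L,13448,up**,up*,down*
M,13627,,up*,
N,13705,up*,,
O,15292,up*,,
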