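Speract
SR
GC
cGMP
PDE
KCNG
NHE
HCN
cAMPCC
LVA
HVA
CaCC
CaKC
CaP
NCE
dK
dNa
dCl
dCa
V
Ca
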