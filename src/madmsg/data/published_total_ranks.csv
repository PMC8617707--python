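message_id,self_report,lab
H1,1,12
H2,5,1
HS1,4,10
HS2,1,6
HF1,7,8
HF2,3,3
A1,6,4
A2,8,9
AS1,9,5
AS2,12,7
AF1,11,2
AF2,9,11
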