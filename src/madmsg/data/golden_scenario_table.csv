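message_id,equal_attributes_score,equal_attributes_rank,equal_studies_score,equal_studies_rank,prefer_self_report_score,prefer_self_report_rank,prefer_lab_score,prefer_lab_rank
H1,4.0,3,6.5,5 *,4.4,4,4.75,4 *
H2,4.4,4,3.0,1 *,3.6,3,4.75,4 *
HS1,5.7,5,7.0,7 *,5.0,5 *,7.25,7 *
HS2,3.6,1 *,3.5,3,3.2,1 *,4.00,2
HF1,6.6,7,7.5,9,6.4,7,7.25,7 *
HF2,3.6,1 *,3.0,1 *,3.2,1 *,3.75,1
A1,5.9,6,5.0,4,5.0,5 *,6.50,6
A2,7.7,9,8.5,10,8.4,8,7.25,7 *
AS1,9.6,11,7.0,7 *,8.8,9 *,9.25,11
AS2,9.1,10,9.5,11,10.2,12,8.00,10
AF1,7.0,8,6.5,5 *,8.8,9 *,4.50,3
AF2,10.0,12,10.0,12,10.0,11,10.00,12
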