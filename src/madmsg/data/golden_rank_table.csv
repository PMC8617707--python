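message_id,receptivity_mean,receptivity_rank,engagement_mean,engagement_rank,positive_attitude_mean,positive_attitude_rank,negative_emotion_mean,negative_emotion_rank,self_report_total,self_report_total_rank,hr_deceleration_mean,hr_deceleration_rank,recognition_accuracy_mean,recognition_accuracy_rank,visual_attention_mean,visual_attention_rank,lab_total,lab_total_rank
H1,5.29,1,5.77,4,4.86,3,2.2,2,10,1,2.82,4,0.871,2,1220.72,12,18,12
H2,4.92,6,5.94,1,4.53,7,2.04,3,17,5,2.87,3,0.677,10,1375.4,1,14,1
HS1,5.15,2,5.74,6,4.85,4,2.04,3,15,4,2.45,6,0.698,9,1287.5,10,25,10
HS2,5.04,4,5.78,3,4.98,2,2.23,1,10,1,2.16,8,0.878,1,1298.62,6,15,6
HF1,4.89,7,5.74,6,4.64,5,1.99,6,24,7,2.24,7,0.765,7,1293.23,8,22,8
HF2,5.1,3,5.77,4,5.01,1,2.01,5,13,3,2.6,5,0.798,4,1335.34,3,12,3
A1,5.01,5,5.81,2,4.54,6,1.88,8,21,6,1.65,10,0.769,6,1317.9,4,20,4
A2,4.71,8,5.63,10,4.51,9,1.99,6,33,8,1.98,9,0.803,3,1289.96,9,21,9
AS1,4.5,11,5.56,11,4.53,7,1.81,10,39,9,1.64,11,0.517,12,1317.12,5,28,5
AS2,4.1,12,5.73,8,4.23,12,1.73,12,44,12,2.88,2,0.643,11,1295.01,7,20,7
AF1,4.57,10,5.38,12,4.47,11,1.83,9,42,11,3.03,1,0.798,4,1344.93,2,7,2
AF2,4.63,9,5.64,9,4.48,10,1.74,11,39,9,1.47,12,0.727,8,1261.06,11,31,11
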