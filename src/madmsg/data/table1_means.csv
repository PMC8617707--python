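message_id,receptivity,engagement,positive_attitude,negative_emotion,hr_deceleration,recognition_accuracy,visual_attention
H1,5.29,5.77,4.86,2.20,2.82,0.871,1220.72
H2,4.92,5.94,4.53,2.04,2.87,0.677,1375.4
HS1,5.15,5.74,4.85,2.04,2.45,0.698,1287.5
HS2,5.04,5.78,4.98,2.23,2.16,0.878,1298.62
HF1,4.89,5.74,4.64,1.99,2.24,0.765,1293.23
HF2,5.10,5.77,5.01,2.01,2.60,0.798,1335.34
A1,5.01,5.81,4.54,1.88,1.65,0.769,1317.9
A2,4.71,5.63,4.51,1.99,1.98,0.803,1289.96
AS1,4.50,5.56,4.53,1.81,1.64,0.517,1317.12
AS2,4.10,5.73,4.23,1.73,2.88,0.643,1295.01
AF1,4.57,5.38,4.47,1.83,3.03,0.798,1344.93
AF2,4.63,5.64,4.48,1.74,1.47,0.727,1261.06
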