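name,study,direction
receptivity,self_report,higher
engagement,self_report,higher
positive_attitude,self_report,higher
negative_emotion,self_report,higher
hr_deceleration,lab,higher
recognition_accuracy,lab,higher
visual_attention,lab,higher
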