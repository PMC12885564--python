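feature,m1,m2,m3,m4,m5
blood_pressure,1,2,4,1,3
cholesterol,1,8,2,15,1
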