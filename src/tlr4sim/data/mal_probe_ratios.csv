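probe_id,animal_id,ratio
Ssc.17204.1.S1_at,animal1,0.959
Ssc.17204.1.S1_at,animal2,1.301
Ssc.17204.1.S1_at,animal3,0.848
Ssc.18913.1.S1_at,animal1,1.270
Ssc.18913.1.S1_at,animal2,0.7956
Ssc.18913.1.S1_at,animal3,1.511
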