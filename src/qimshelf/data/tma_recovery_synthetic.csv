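level,day,replicate,true_spike,measured
LL,1,1,0.5,0.4665
LL,1,2,0.5,0.4665
LL,1,3,0.5,0.4665
LL,2,1,0.5,0.4665
LL,2,2,0.5,0.4665
LL,2,3,0.5,0.4665
ML,1,1,7.5,7.35
ML,1,2,7.5,7.35
ML,1,3,7.5,7.35
ML,2,1,7.5,7.35
ML,2,2,7.5,7.35
ML,2,3,7.5,7.35
HL,1,1,14.0,13.86
HL,1,2,14.0,13.86
HL,1,3,14.0,13.86
HL,2,1,14.0,13.86
HL,2,2,14.0,13.86
HL,2,3,14.0,13.86
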