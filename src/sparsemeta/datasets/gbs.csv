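label,events_treatment,nonevents_treatment,events_control,nonevents_control
Meche,0,74,12,61
Bril,0,26,0,24
PSGBS,3,127,18,103
Nomura,1,22,1,23
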