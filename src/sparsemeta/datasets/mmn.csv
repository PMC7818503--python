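label,events_treatment,nonevents_treatment,events_control,nonevents_control
Azulay,0,5,0,5
Berg,3,3,0,6
Leger,4,3,2,5
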