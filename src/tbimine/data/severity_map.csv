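pattern,category,priority
S065,severe,1
S062,moderate,2
S061,mild,3
S060,unspecified,4
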