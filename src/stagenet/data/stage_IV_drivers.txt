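GSK3B
GGT1
EIF2B5
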