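ESR1
SNCG
PTCH1
MUC1
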