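>g_rich_ir_synthetic
A 10 10 10 10 10 1 0 0 0 1
C 0 0 0 1 0 0 1 0 0 0
G 1 1 1 1 2 11 11 12 12 10
T 1 1 1 0 0 0 0 0 0 1
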