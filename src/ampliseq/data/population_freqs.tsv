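variant	maf
V470M	0.42
L467F	0.002
R668C	0.003
R1070Q	0.001
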