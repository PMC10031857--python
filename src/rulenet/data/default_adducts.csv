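name,mass_shift,charge,multiplicity
[M+H]+,1.007276466,1,1
[M-H]-,-1.007276466,-1,1
[M+Na]+,22.989220702,1,1
[2M+H]+,1.007276466,1,2
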