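group,rt_um,fd_um,irlt_um,fda
C,185,121,8,13
PG1,180,119,5,21
PG2,218,78,23,5
PG3,322,12,84,2
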