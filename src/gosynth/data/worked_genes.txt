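G01
G02
G03
G04
G05
G06
G07
G08
G09
G10
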