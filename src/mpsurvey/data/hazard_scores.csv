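polymer,score
PE,11
PP,1
PET,4
PA,47
NYLON,47
PU,7384
PAN,10599
EVA,9
PCT,4
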