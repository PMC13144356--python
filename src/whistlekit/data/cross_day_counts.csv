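category,2023-07-20,2023-07-26,2023-07-28
A,6,93,131
O,35,0,7
S,0,3,5
U,3,0,64
Z,28,5,374
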