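element,mass
C,12.0
H,1.0078250319
N,14.0030740052
O,15.9949146221
S,31.97207069
P,30.97376151
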