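label,rt
L-Ala,8.661
D-Ala,10.377
L-Ser,6.379
D-Ser,6.660
Gly,7.922
L-Glu,7.831
D-Glu,8.807
L-Asp,7.100
D-Asp,7.900
L-Thr,6.775
D-Thr,8.816
L-allo-Thr,6.941
D-allo-Thr,7.845
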