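code,formula,default_chirality,kind
Gly,C2H3NO,achiral,amino_acid
Ala,C3H5NO,L,amino_acid
Ser,C3H5NO2,L,amino_acid
Pro,C5H7NO,L,amino_acid
Val,C5H9NO,L,amino_acid
Thr,C4H7NO2,L,amino_acid
Cys,C3H5NOS,L,amino_acid
Leu,C6H11NO,L,amino_acid
Ile,C6H11NO,L,amino_acid
Asn,C4H6N2O2,L,amino_acid
Asp,C4H5NO3,L,amino_acid
Gln,C5H8N2O2,L,amino_acid
Lys,C6H12N2O,L,amino_acid
Glu,C5H7NO3,L,amino_acid
Met,C5H9NOS,L,amino_acid
His,C6H7N3O,L,amino_acid
Phe,C9H9NO,L,amino_acid
Arg,C6H12N4O,L,amino_acid
Tyr,C9H9NO2,L,amino_acid
Trp,C11H10N2O,L,amino_acid
allo-Thr,C4H7NO2,L,amino_acid
Homoser,C4H7NO2,L,amino_acid
HMHDA,C17H32O2,unspecified,lipid
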