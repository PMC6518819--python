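# nrpsmine

Genome mining and structure verification for fungal NRPS–PKS
lipodepsipeptide clusters.

Filamentous fungi assemble cyclic lipodepsipeptides — a peptide ring closed
through an ester bond onto a β-hydroxy fatty acid — on giant nonribosomal
peptide synthetases (NRPS) working alongside a type I polyketide synthase
that builds the lipid. Connecting such a gene cluster to the compound it
makes requires two complementary chains of inference, and this package
implements both:

**From the gene to a predicted structure.** The NRPS protein is parsed into
its modular domain grammar — an optional initiation PCP that loads the
activated fatty acid, repeated condensation–adenylation–carrier
(C-A-PCP) elongation blocks with optional epimerization (E) domains, and a
terminal condensation domain (C<sub>T</sub>) that releases and cyclizes the
product. Each adenylation domain's substrate is predicted from its
eight-residue binding-pocket signature (the Stachelhaus code, read at
GrsA-PheA reference positions 235, 236, 239, 278, 299, 301, 322, 330 via
global alignment to a reference A domain). The collinearity rule then maps
module order onto residue order; E-bearing modules contribute D-configured
residues. Missing domains are recovered by scanning position-specific
scoring profiles built from the cluster's own domains, with shuffle-based
empirical p-values.

**From the compound back to the gene.** A candidate structure is verified
by exact monoisotopic mass (electron-mass-corrected [M+H]⁺ values to four
decimal places), by its b/y fragment-ion ladder — walking the descending
b-series of the hydrolysed (ring-opened) peptide reads off the residue-loss
sequence — and by Marfey's method: L-FDAA-derivatized hydrolysate amino
acids are assigned D/L configurations from LC retention times against a
standards table, including L:D ratios from ion-chromatogram areas.

A synthetic-data module generates every input the pipeline needs —
reference A domains with planted pocket codes, multi-module NRPS proteins,
jittered MS2 peak lists with decoys, Marfey chromatogram tables — with full
ground truth, so the whole chain is testable end to end.

## Worked example

The package ships the residue library and specificity-code table for the
*Phoma* sp. cluster whose product is the cyclic lipodepsipeptide
cyclo-[HMHDA-L-Ala-L-Glu-L-Asn-L-Ser-L-Ser-D-Ser-D-allo-Thr-Gly]
(HMHDA = β-hydroxy-γ-methyl hexadecanoic acid):

```python
from nrpsmine import build_peptide, hydrolyze, ion_mz, IonSpec, parse_formula
from nrpsmine.fragments import PeakList, Peak, infer_losses
from nrpsmine.residues import residue_library

cyclic = build_peptide(
    ["HMHDA", "Ala", "Glu", "Asn", "Ser", "Ser", "Ser", "allo-Thr", "Gly"],
    "macrolactone",
)
print(cyclic.formula)                                            # C44H75N9O17
print(f"{ion_mz(IonSpec(cyclic.formula + parse_formula('H'), 1)):.4f}")
#   1002.5354   <- calcd [M+H]+ of the cyclic form
linear = hydrolyze(cyclic)
print(f"{ion_mz(IonSpec(linear.formula + parse_formula('H'), 1)):.4f}")
#   1020.5459   <- calcd [M+H]+ after ring opening (+H2O)

obs = PeakList([Peak(m) for m in
                (945.5139, 844.4662, 757.4342, 670.4022,
                 583.3701, 469.3272, 340.2846)])
print(infer_losses(obs, residue_library(), parent_mz=1020.5459))
#   ['Gly', 'Thr', 'Ser', 'Ser', 'Ser', 'Asn', 'Glu']
```

The seven observed b-ions read off the C-terminal-to-N-terminal residue
losses, fixing the peptide sequence; the remaining b2 ion (340.2846) is
the lipid plus the first amino acid. The mass-isobaric Thr/allo-Thr pair
is then resolved chromatographically (`nrpsmine.marfey`), and the gene-side
prediction (`nrpsmine.cluster.predict_product` over the parsed
architecture and the packaged code table) returns the same structure,
stereochemistry included.

A command-line interface mirrors the library
(`nrpsmine mass | fragments | match | code | scan | architecture |
recover-domain | classify-c | predict | marfey | simulate | full`), e.g.

```sh
nrpsmine mass --formula C44H75N9O17 --adduct +H     # -> 1002.5354
nrpsmine simulate --seed 12 --out demo --decoys 20
nrpsmine full --dir demo                            # round-trip report
```

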