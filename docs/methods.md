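# Methods

This note records the models, conventions and parameter choices behind
`nrpsmine`, and what the synthetic generators do and do not emulate.

## Mass conventions

Masses are monoisotopic: each element contributes the mass of its most
abundant isotope (packaged table, ≥ 6 decimal places: C 12.000000,
H 1.00782503, N 14.00307401, O 15.99491462, S 31.97207069, P 30.97376151).
Positive-ion m/z is computed as (mass − z·mₑ)/z with the electron mass
mₑ = 0.00054858 Da subtracted per charge; the ion's formula already
includes its protons as H atoms. The electron correction matters at the
fourth decimal place for singly charged ions (~0.0005 Th) and is required
to reproduce high-resolution "calcd" values exactly. Formula strings are
written in Hill order (C, H, then alphabetical), so parsing and writing
round-trip. Printed-value comparisons in tests use ±0.0005 Da after
rounding to 4 dp, since last-digit rounding conventions differ between
tools.

## Residues and depsipeptide accounting

Residues are stored as in-chain formulas (free monomer minus one water).
A linear peptide is Σ residues + H₂O; a macrolactone is exactly
Σ residues, because ring closure through the ester between the lipid
β-hydroxyl and the C-terminal carboxyl removes the one water the linear
form retains. The lipid HMHDA (β-hydroxy-γ-methyl hexadecanoic acid,
free acid C₁₇H₃₄O₃) is modelled as an ordinary residue of in-chain formula
C₁₇H₃₂O₂, which makes cyclic-form accounting uniform with no special
cases and reproduces both parent masses and the lipid-containing b2
fragment. Thr, allo-Thr and homoserine are distinct library entries with
identical formulas: mass cannot separate them, chromatography can.
Chirality is metadata only — it never enters a mass. The empty linear
peptide is one water by the Σ + H₂O convention.

## Fragment ladders and sequencing

Only singly protonated b and y ions are modelled (a/c/z series, internal
fragments, neutral losses and multiple charging are out of scope). With
the residue accounting above, b_i = Σ residues(1..i) + H⁺ and
y_j = Σ residues(n−j+1..n) + H₂O + H⁺, giving the exact complementarity
identity mz(b_i) + mz(y_{n−i}) = mz([M+H]⁺) + mz(H⁺).

Peak-to-ladder matching is greedy nearest-match within a ppm tolerance
(default 5 ppm, comfortably above the ≤ 2 ppm instrument errors of the
motivating data), assigning candidate pairs in order of increasing |ppm|
with ties broken b-before-y, then lower index; each peak and fragment is
used once.

Ladder sequencing walks the descending b-series from the protonated
parent: the first step loses one residue plus water, every later step one
residue, each matched to the library within 0.01 Da. Two modes exist:

* **strict** (default): every peak below the current position must
  continue the ladder; an unmatched step raises an error reporting the
  step mass. Right for curated peak lists.
* **decoy-tolerant** (`skip_unmatched=True`): among all residue-sized
  step chains the longest wins; equal-length chains are ranked by smaller
  cumulative |mass residual|, which separates true ladder peaks
  (instrument-accuracy residuals) from decoys that barely fall inside the
  window. Right for raw peak lists.

Mass-isobaric residues matching one step are reported as a single
ambiguity set resolved by library insertion order (so "Thr" stands for
the Thr/allo-Thr/homoserine triple); distinct masses inside the window
raise an ambiguity error instead of guessing.

## Specificity codes

The substrate signature of an adenylation domain is read by global
Needleman–Wunsch alignment (BLOSUM62, affine gaps, open 10 / extend 1 —
configurable) of the query against a reference A domain, taking the query
letters in the columns of the eight reference pocket positions
(GrsA-PheA numbering 235, 236, 239, 278, 299, 301, 322, 330; positions are
1-based over the ungapped reference). Among co-optimal alignments the
aligner's first enumeration is taken as canonical — determinism is what
downstream code relies on, not a particular gap-placement preference.
A pocket column holding a query gap yields '-'; more than four gapped
positions raise a low-confidence error rather than returning a junk code.

Prediction is exact table lookup first, then nearest-neighbour under
Hamming distance (ties alphabetical by label; gapped codes are rejected).
The packaged table carries exactly the six characterised codes of the
motivating cluster (Ala, Glu, Asn, Ser, Thr, Gly), provenance-tagged;
users extend it via TSV. No external specificity database is bundled, and
no machine-learning predictor is attempted.

## Cluster annotation

Domain evidence is motif- and profile-based by design — this package does
not reimplement HMMER/Pfam scoring, and significance is a shuffle-based
empirical p-value, not a database E-value. Degenerate motifs use 'x' as a
wildcard and lowercase for weakly conserved positions; the packaged set
covers the ten adenylation core motifs mA1–mA10, the condensation motif
HHxxxDG with its SHxxxDG/SHxxxDA variants (flagged non-canonical), and
the epimerization motif HHxxxDxVSW.

Profiles are per-column log-odds (base 2) over the 20-letter alphabet
with Laplace pseudocounts (weight 1 spread by the background, uniform by
default); columns at least half gap are dropped. Scanning slides the
profile ungapped along the target and reports the best window; the
empirical p uses the (k+1)/(n+1) estimator over n residue-shuffled
targets, so the smallest attainable p with 1000 shuffles is 1/1001.

The module grammar is: optional initiation PCP; repeated [C A PCP (E)?]
blocks; optional trailing C_T. The parser is total — out-of-grammar
domains produce diagnostics, never exceptions — and flags an elongation
module lacking its C domain as incomplete, reporting the inter-domain
interval (end of the previous module's last domain + 1, start of the A
domain − 1; possibly empty when domains are contiguous) in which to
profile-search for the missing domain. Coordinates are 1-based inclusive
throughout.

Condensation-subtype classification scores a sequence under user-supplied
subtype profiles and reports the ranking with the top-two margin (flagged
ambiguous under 1 bit, optionally unclassified by shuffle p-value). It
never asserts a resolved subtype truth: in the motivating system the
subtype evidence was internally contradictory, and stereochemistry is
instead taken from E-domain placement, which matches the experimental
Marfey assignments. Accordingly `predict_product` configures a residue D
exactly when its module carries an E domain (Gly stays achiral), prepends
the lipid when an initiation PCP is present, and closes the macrolactone
when a C_T terminates the gene. Mass-isobaric isoforms the code table
cannot see (Thr vs allo-Thr) are substituted through an explicit
`isoform_map` once chromatographic evidence resolves them — the package
never silently upgrades a prediction.

## Marfey assignment

Sample peaks are assigned to the nearest derivatized standard within a
retention-time tolerance (default 0.05 min; the closest pair in the
packaged standards, L-Ser 6.379 vs D-Ser 6.660 min, is an order of
magnitude wider). Two standards whose |Δrt| differ by less than the
resolution parameter (0.02 min) flag the peak ambiguous rather than
choosing. L:D ratios reduce peak areas to the smallest integer ratio
within 15% relative tolerance. Consistency checking maps the product side
through acid hydrolysis (Asn→Asp, Gln→Glu), groups Thr-family isoforms,
excludes the underivatized lipid, marks achiral residues untestable, and
requires observed analytes (isoform + chirality) and area ratios to match
the product's multiplicities.

## Synthetic data

The generators are pure functions of (spec, seed); each draws from its own
named substream so adding a generator never shifts another's stream. The
reference A domain (~550 aa) carries mA1–mA10 in order with the eight
pocket positions spread through a 100-residue mA4–mA5 region, mirroring
where the signature lives in real A domains. Cluster assembly plants each
module's code at the mapped pocket positions and mutates the rest of the
anchor at 5% substitution and 2% indel rate, with indels excluded from
±5-column pocket neighbourhoods — enough noise to stress the aligner
while keeping extraction well-posed. MS2 simulation jitters the true
ladder by ≤ 3 ppm (default) and adds uniform decoys; Marfey simulation
emits one peak per chiral analyte at the standard's retention time with
areas proportional to multiplicity and Asn emitted as Asp. Random test
clusters draw residues from a mass-distinct pool (no Ile/Leu or
Thr/allo-Thr/homoserine collisions) so ladder walking has a unique answer.

What the generators do **not** emulate: real inter-domain linker
composition and length variation, genuine domain sequence families (PCPs
are random strings with known coordinates, so domain *detection* from
sequence alone is exercised only via motifs/profiles, not learned from
the generator), intensity structure of spectra, co-eluting Marfey peaks,
and nucleotide-level gene structure. Passing round-trip tests therefore
demonstrates correctness of the inference machinery under controlled
noise, not performance on raw genomic or instrument data.

## Problem sizes and determinism

The statistical checks run at fixed seeds: 200 single-module clusters for
code-recovery rate, 50 random clusters for the end-to-end round trip,
1000 shuffles for profile significance, 100 random peptides for the
complementarity and self-sequencing properties. The full suite completes
in well under a minute on one CPU. `scripts/acceptance.py` takes a single
`--seed` that drives its synthetic health check; the printed-value
recomputations are deterministic.

## Known limitations

* Alignment-based code extraction assumes the query is a full A domain
  homologous to the anchor; heavily truncated domains trip the
  low-confidence guard rather than recovering partial codes.
* Profile scanning is ungapped; an insertion inside a domain splits its
  score across windows.
* The D-configuration rule is purely architectural (E-domain presence);
  trans-acting epimerases or dual-function C domains would be missed.
* Only singly charged ions; peptides whose spectra are dominated by
  doubly charged fragments need preprocessing.
* The ratio reducer caps integer parts at 6 and 15% tolerance; strongly
  skewed ionization efficiencies between stereoisomers would defeat
  area-based multiplicity inference.
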