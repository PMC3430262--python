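# Methods

## Coordinates, symbols and input contract

All alignment coordinates are 1-based, closed intervals ("an insertion at
position 514" names a column, not an offset). Inputs arrive pre-aligned;
the package never realigns. Rows may contain the four bases, IUPAC
ambiguity codes, `N` and `-`; `.` and `~` are normalised to `-` at parse
time and case is folded. Ambiguity codes and `N` are retained losslessly in
the matrices and treated as missing data wherever characters are compared
(distances, VC/PIC counting). A run of `-` interrupted by `N` is two gap
runs: a missing base is not evidence of a length mutation.

## Gap annotation and indel identity

A *gap region* is a maximal run of `-` in one row. Two gap regions
represent the same *indel* exactly when they share both termini (start and
end column); identity ignores which rows carry the gap. Runs touching the
first or last column are *terminal* and, by default
(`terminal_gap_policy="exclude"`), are treated as missing data rather than
indels: in amplicon data, sequences of very different recovered lengths
imply leading/trailing gaps that reflect sequencing coverage, not length
mutations, and coding them would fabricate characters. For datasets with
full-length coverage the `include` policy codes them like any other run.

Pairwise relations between indels are classified as identical, nested
(one span inside the other, shared terminus allowed), straddling-overlap
(intersecting, neither containing) or disjoint. Overlap-connected
components are found by a sort-and-sweep over intervals.

## SIC scoring

For each distinct indel *(s, e)*, a sequence scores

- `1` (present) if it has a gap run exactly spanning *(s, e)*;
- *inapplicable* if one of its gap runs strictly contains *(s, e)* — the
  longer deletion destroys the evidence either way;
- *missing* if a terminal run (under the exclude policy) covers *(s, e)* —
  the region was simply not sequenced;
- `0` (absent) otherwise, including partial overlaps, which by the termini
  rule are different indels.

## MCIC scoring and step matrices

Each overlap-connected component becomes one multistate character. A
sequence's state is the exact subset of component-member spans it carries;
the no-gap pattern is always state 0, and a sequence whose terminal missing
region covers the whole component span is inapplicable. Step-matrix costs
are the minimum number of indel events transforming one gap pattern into
another, computed as an assignment problem over gap runs: matching identical
runs is free, matching overlapping runs costs one (a boundary shift),
matching disjoint runs costs two (loss plus gain), and unmatched runs cost
one each. The construction is symmetric with zero diagonal. Distance-based
analyses use only state identity; the step matrices are emitted in the
NEXUS `ASSUMPTIONS` block (one `USERTYPE` per character) for parsimony
programs.

## The four treatments and character accounting

`build_extended_matrix` realises CD (delete every column containing any
gap, no coded part), PWD (matrix untouched; deletion deferred to the
distance step), and SIC/MCIC (full matrix plus coded block). Under SIC the
total character count is always the aligned length plus the number of
distinct indels.

Variable characters (VC, ≥2 distinct states) and parsimony-informative
characters (PIC, ≥2 states each carried by ≥2 sequences) are counted per
character. Nucleotide columns containing any gap are excluded from the
counts in **every** scheme: their length variation is carried by the coded
characters and must not be double-counted as substitution variability, and
this convention is what makes the CD and PWD views report identical counts
(the orderings VC/PIC: CD = PWD ≤ MCIC ≤ SIC then follow structurally, with
strictness whenever overlapping indels exist and the affected characters
are variable/informative). Percentages are reported to two decimals of the
scheme's own total length.

## Distances, summaries, haplotypes

The p-distance of a pair is (differing usable characters)/(usable
characters), where usable excludes gaps, `N`, ambiguity codes and
inapplicable or missing coded states — per pair under pairwise deletion, or
globally under complete deletion. A coded character counts as one character.
CD analyses default to complete deletion; PWD/SIC/MCIC to pairwise deletion
(complete deletion after coding would discard the very columns whose indels
were coded, double-penalising them). A pair with zero usable characters is
an error naming the pair; bootstrap replicates in which this occurs are
discarded and logged, and more than 10% discarded aborts the run.

The hierarchical summary pools, per species: within-population pairs
(populations with a single sampled individual contribute no pairs and are
thereby excluded, mirroring the standard practice of dropping singleton
populations from intra-population statistics), between-population
conspecific pairs, and all conspecific pairs; each is reported as mean and
min–max range to five significant figures. The global intraspecific mean is
the unweighted mean of per-species means (so that it pairs naturally with a
per-species range); the interspecific mean averages all heterospecific
pairs, with a per-species-pair-means alternative behind
`interspecific_mode="species-pairs"`. Haplotypes are distinct aligned row
strings among conspecific individuals, gaps included — an indel-centric
analysis must let gaps differentiate haplotypes.

## Neighbor-joining and bootstrap

Classical NJ (Q-criterion agglomeration). Ties in the Q minimum are broken
deterministically by the lowest (row, column) pair in current order, so
reruns are reproducible without randomness. Negative limb lengths are
clamped to zero with the deficit moved to the sibling limb, preserving the
joined pair's distance; the final three limbs use the closed form. On
additive matrices the reconstruction is exact (topology and branch
lengths), which the tests verify against an independent random-additive-tree
oracle and against an external NJ implementation.

Bootstrap resamples *characters* — nucleotide columns and coded indel
characters as equal units — because the coded characters are precisely the
manipulation whose effect on support is being measured; resampling only
nucleotide columns would freeze the indel signal across replicates. Support
of each internal edge of the original-matrix tree is the percentage of
valid replicate trees containing the same bipartition (edge-frequency
supports); a >50% majority-rule consensus tree is available behind
`method="consensus"`. Defaults: 1000 replicates (a tenfold-larger count is
a flag away; tests use 200); the tests and examples in this repository use
desk-scale replicate counts and alignments of a few hundred columns so the
full suite runs in well under a minute of bootstrap time.

## Discrimination

"Clade" on an unrooted tree is operationalised as a bipartition. A species
is monophyletic iff the split isolating exactly its individuals exists, and
distinguished iff that split's support is strictly greater than the
threshold (default 50%). The report separates non-monophyly from
insufficient support rather than collapsing both into one "not
distinguished" symbol. Single-individual species are trivially monophyletic
(the trivial split is in every tree, support 100) and flagged as singletons.
Resolution is 100 × distinguished/species to one decimal. The indel-only
mode ignores nucleotide columns entirely: a species is distinguished iff
some coded character has all of its individuals sharing one definite state
carried by no other individual (a private diagnostic indel), and the
diagnostic spans are listed.

## Synthetic data

The generator emulates a hierarchical barcoding study: each species gets a
uniform 3–8 populations of 2–3 individuals (defaults; nine species, two
spacer-like loci of 820 and 950 columns). A random ancestral sequence
evolves down a random (or supplied) species topology with per-branch
per-site Bernoulli substitutions, then through population and individual
branches. Default branch probabilities (stem 1.2e-3, population 2.5e-4,
individual 1.5e-4 per site) were chosen so mean interspecific p-distances
fall in roughly 0.003–0.01 and intraspecific means near 0–0.001 — the
regime in which substitution signal is marginal and indel treatment matters.
Indels are simulated directly in alignment coordinates as gap masks:
diagnostic deletions on species stems (non-overlapping, internal, separated
by at least one column so termini stay distinct and runs never merge);
nuisance deletions on random species-tree clades (which may nest or overlap
anything); and mononucleotide-repeat slippage — a planted 5-base repeat
whose last unit contracts independently per terminal branch with a given
rate, the classic homoplasy source. Slippage sites are kept one column
clear of diagnostic spans so a contraction can never merge with a planted
diagnostic gap and silently change its termini. Every simulated event is
recorded in a truth record (branch, span, kind, plus the expected
diagnostic characters per species) for recovery tests.

What the generator does **not** emulate: alignment error (homology is exact
by construction, so passing tests say nothing about CLUSTAL/MAFFT artefacts
on real spacers), coalescent gene-tree/species-tree discordance,
insertions as such (all length variation is represented as deletions
relative to the longest state, which is equivalent up to relabelling in
alignment coordinates), rate heterogeneity along the sequence, and base
composition structure.

The planted test fixture (four species, 600 columns, three diagnostic
indels of 4–12 bp per species, stem substitution probability 3e-4, slippage
at three sites) deliberately sits in the regime the package exists for:
substitution signal too weak and too homoplasious for CD to resolve the
species, diagnostic indels decisive under SIC/MCIC. Three diagnostics per
species keep bootstrap supports near 95% — with k diagnostic characters the
probability a replicate retains at least one is about 1 − e^−k — which
makes the cross-seed reproducibility check (±3 points at 1000 replicates)
a >3-standard-deviation bound rather than a coin flip.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.default_rng` seeds; pipeline
  stages derive per-(locus, scheme) seeds from the run seed via a CRC of the
  stage key and `SeedSequence`, stable across processes.
- All-equal distance matrices resolve deterministically under the tie-break;
  the result is an arbitrary but reproducible topology.
- Bootstrap supports are rounded to 0.1; resolution percentages to 0.1;
  VC/PIC percentages to 0.01; distances print at 5 significant figures.
- Zero-length branches are written as `0.000000`, never negative.
- Empty coded blocks (gap-free loci) are valid everywhere: the four schemes
  then produce identical matrices and identical counts.

## Known limitations

- MCIC step-matrix costs implement a minimum-event scheme chosen here
  (assignment over gap runs); published cost schemes differ in detail.
  Distances and trees are unaffected (state identity only); only NEXUS
  interchange carries the costs.
- NEXUS output uses the `MIXED(DNA:…,STANDARD:…)` datatype extension, which
  some older programs do not parse.
- `assess_species` evaluates exact species bipartitions only; paraphyly
  with respect to a single intruder is reported simply as non-monophyly.
- The concatenated analysis assumes locus boundaries are honest (no indel
  spans two loci), which the per-locus coding enforces by construction.
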