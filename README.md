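# indelbarcode

Indel (gap) coding, p-distance neighbor-joining trees and
species-discrimination scoring for DNA barcoding of closely related taxa.

## The problem

Closely related plant species — congeners separated by very recent
divergence — often differ by almost no substitutions in the standard
barcoding loci. Noncoding chloroplast spacers do, however, accumulate
insertions and deletions, and an indel fixed in one species can identify it
when base substitutions cannot. Most barcoding workflows throw that signal
away: columns containing gaps are deleted outright (*complete deletion*, CD)
or skipped pair by pair (*pairwise deletion*, PWD). `indelbarcode`
implements the two standard ways of keeping the signal:

- **Simple indel coding (SIC).** Every indel with a distinct pair of 5′/3′
  termini becomes one binary presence/absence character appended to the
  matrix. A sequence whose longer gap strictly contains a smaller indel is
  scored *inapplicable* for the smaller character. An alignment of length
  *L* with *k* distinct indels yields an extended matrix of *L + k*
  characters.
- **Modified complex indel coding (MCIC).** Overlap-connected indels merge
  into a single multistate character whose states are the observed gap
  patterns; each character carries a symmetric minimum-event step matrix
  (zero diagonal) for parsimony interchange.

Around the coders the package provides the full comparison pipeline: gap-run
annotation and the distinct-termini indel inventory; p-distances under
complete or pairwise deletion, with coded indel characters counted as single
characters; hierarchical distance summaries (within-population /
between-population / intraspecific / interspecific) and per-species
haplotype counts, for judging how many individuals and populations a
reference library needs; neighbor-joining with nonparametric bootstrap in
which nucleotide columns and coded indel characters are resampled as equal
units; and discrimination scoring — a species is *distinguished* when the
bipartition isolating exactly its individuals appears in the (unrooted) tree
with nodal support strictly above a threshold (default 50%). An
indel-characters-only mode finds *private diagnostic indels*: characters at
which all individuals of one species share a state carried by no one else.

A seeded synthetic-data generator emulates the hierarchical sampling design
such comparisons assume (several species; 3–8 populations each; 2–3
individuals per population; interspecific p-distances of a few per mille;
species-diagnostic indels; homoplasious mononucleotide-repeat slippage), so
every stage is testable without downloading sequence data.

## Worked example

Simulate a four-species dataset with three diagnostic indels per species,
weak substitution signal and slippage homoplasy, then compare all four indel
treatments:

```bash
cat > sim.yaml <<EOF
n_species: 4
pops_per_species: [3, 3]
inds_per_pop: [2, 2]
locus_lengths: {spacer: 600}
diagnostic_indels_per_species: 3
diagnostic_indel_length: [4, 12]
stem_sub_prob: 0.0003
pop_sub_prob: 0.001
tip_sub_prob: 0.0005
slippage_sites_per_locus: 3
slippage_rate: 0.1
EOF
indelbarcode simulate --out data --seed 5 --config sim.yaml
indelbarcode run-all data/spacer.fasta --metadata data/metadata.tsv \
    --scheme CD --scheme PWD --scheme SIC --scheme MCIC \
    --replicates 200 --seed 11 --out results
```

which prints:

```
scheme  n_indels  aligned_length  VC  VC_pct  PIC  PIC_pct  mean_interspecific  mean_intraspecific  support_sp01 support_sp02 support_sp03 support_sp04  resolution_pct resolved
    CD        14             507  16    3.16    7     1.38            0.004593            0.003222          63.0         n.d.         n.d.         61.0            50.0      2/4
   PWD        14             600  16    2.67    7     1.17            0.004983            0.003794          52.5         n.d.         n.d.         n.d.            25.0      1/4
   SIC        14             614  30    4.89   21     3.42            0.016243            0.004385          97.5         94.0         91.0         83.5           100.0      4/4
  MCIC        14             614  30    4.89   21     3.42            0.016243            0.004385          98.5         91.5         90.0         85.5           100.0      4/4
```

Reading the table: the alignment contains 14 distinct indels (12 planted
diagnostics plus slippage contractions). Under CD the gap columns vanish
(507 of 600 columns survive) and only two species reach supported monophyly;
under SIC/MCIC the coded characters raise the variable-character count from
16 to 30 and every species forms a clade with support well above the 50%
rule — `n.d.` marks species whose individuals either do not form a
bipartition of the tree or do so without sufficient support. Per-scheme
artifacts (NEXUS matrix with the coded partition and MCIC step matrices,
newick tree with supports, distance matrix and hierarchical summary,
discrimination reports) land under `results/spacer/<scheme>/`.

The same operations are available as a library:

```python
from indelbarcode import (read_alignment, gap_regions_for,
                          build_extended_matrix, p_distance,
                          bootstrap_support, assess_species)

locus = read_alignment("data/spacer.fasta")
indels = gap_regions_for(locus)              # distinct-termini inventory
matrix = build_extended_matrix(locus, "SIC", indels)
tree = bootstrap_support(matrix, "pairwise", replicates=1000, seed=1)
```

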