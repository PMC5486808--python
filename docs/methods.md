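# Methods

## Coordinate frame

All amino-acid positions are 1-based in the full-protein alignment frame
whose first residue is the first residue of the α1 domain. The MiSeq
exon-3 fragment is 247 nt (or 244 nt with a 3-bp deletion), starts and
ends mid-codon (2-nt overhangs), and covers the 81 complete codons at
positions 93–173; the deletion removes codon 147. Short alleles are
anchored into a common 247-column alignment by placing the deletion gap
at the codon-147 nucleotides (fragment offset 164–166); because the
deletion position is known and the fragment is a single PCR product, a
general-purpose aligner is unnecessary and anchored gap insertion is
exact and deterministic.

The 12-codon PBR partition used for dN/dS is
{96, 98, 112, 114, 121, 149, 151, 154, 155, 159, 162, 166}; the full
exon-3 PBR set and the exon-2 set are exposed as constants for masking.
Of the peptide main-chain consensus sites, only the tyrosine at position
170 is assignable to an alignment position inside the fragment from the
available description of the frame, so the default main-chain
conservation check covers {170: Y} and accepts a user-supplied map for
other primer sets.

## Filtering cascade

Depth gate, clustering, calibration and chimera screen are as described
in the README. Implementation decisions that the informal description of
such cascades leaves open, fixed here:

- "differed by 1–2 bp" is Hamming (substitution) distance between
  equal-length sequences; 244-nt and 247-nt variants never merge, since
  the 3-bp deletion separates true allele classes and the artefact model
  is substitutions only;
- clustering is greedy in depth order (ties lexicographic); a variant
  eligible for several dominants merges into the deepest; the 25% depth
  ratio is taken against the dominant's own depth, not the cluster's
  running depth;
- cluster frequency is cluster depth over total post-demultiplex
  amplicon depth, computed after merging and before chimera removal
  (the most conservative denominator);
- the chimera screen runs before threshold filtering and removes flagged
  clusters regardless of frequency, so a chimera above the threshold can
  never be called;
- calibration maximizes (number of exactly matching duplicate pairs,
  mean Jaccard) lexicographically over the grid 0.5–10% in 0.1% steps
  and returns the *smallest* optimal threshold, retaining maximal allele
  diversity at equal concordance;
- when duplicates disagree at the chosen threshold, the genotype is
  taken from the deeper amplicon and the individual is flagged.

## Validation

Translation trims the 2-nt overhangs and rejects internal stops (the
allele is retained in reports, flagged non-functional). Protein classes
are identical-translation groups; naming is depth-ranked then
lexicographic, `UA*01`-style, stable under re-runs and extendable
against an existing registry. Alleles observed in a single individual
are retained if they pass all filters. When building codon alignments,
sequences that become identical after the overhang trim are collapsed
onto the first-seen id (incomplete codons carry no information for
codon-level statistics).

## Diversity and divergence

π is the mean pairwise per-site p-distance; *S* counts columns with ≥ 2
distinct non-gap states. Gaps are handled by pairwise deletion
throughout so the deletion column does not erase codon-147 information
from long×long pairs; this can differ slightly from complete-deletion
implementations. Nucleotide divergence uses K2P with gamma rate
correction (α = 1), amino-acid divergence uses p-distance; both report
the mean over all pairs with an SE from site-resampled bootstrap
(default 1000 replicates, seeded).

Nei–Gojobori counting: per-codon potential sites are normalized so
synonymous + nonsynonymous = 3 (substitutions creating stops count as
nonsynonymous); multi-step codon differences average over all mutational
pathways, pathways through stops counted as nonsynonymous steps. Per
pair, proportions are Jukes–Cantor corrected; pairs with uncorrectable
proportions (≥ 3/4) are excluded with a warning; dN and dS are means
over pairs; SEs come from codon-resampled bootstrap, and a one-tailed
Z-test of dN > dS uses the bootstrap variance of dN − dS. This matches
the standard pathway-counting lineage of the method; agreement with an
independent implementation (Biopython's NG86) is exact and enforced in
the test suite.

## Per-site selection

The counting (SLAC-style) test uses an NJ tree on K2P distances (pairs
undefined under K2P fall back to p-distance; negative NJ branch-length
estimates are clamped to zero). Ancestral codons are reconstructed per
site by Fitch/Hartigan parsimony over the 64-codon state space, gapped
leaves uninformative; ties resolve by minimizing implied nonsynonymous
changes, then lexicographically. Observed per-site synonymous and
nonsynonymous changes are summed along branches (pathway-averaged); the
neutral synonymous fraction is the mean synonymous share of potential
sites over the observed codons; the p-value is a two-tailed binomial
test of the (rounded) observed synonymous count; classification at
P = 0.1 by the sign of the normalized dN − dS. Only this counting member
is implemented — likelihood fixed/random-effects methods and
recombination-aware trees are out of scope, and site lists from method
ensembles on other trees are not expected to match site-for-site.

## Synthetic data

The generator emulates the study conditions: 38 long + 9 short alleles,
84 individuals, 1–4 loci each (two allele draws per locus with
replacement), 6 technical duplicate pairs (independent redraws from the
same genotype), negative-binomial per-amplicon depths with mean 11,000.
Values without a stated counterpart are modelling choices, fixed once:
depth dispersion 20 (overdispersed enough to exercise the 4000-read
gate), per-read PCR artefact probability 0.02 (each artefact 1 or 2
substitutions, 3:1), per-read chimera probability 0.003 (placing
realized chimera-cluster frequencies well below 1%), and lognormal
per-allele amplification bias with σ = 0.3 on the log scale — the true
bias law of multi-template PCR is not known and this is flagged as the
weakest realism assumption. Allele pools concentrate nonsynonymous
variation at the PBR codons (substitution probability 0.5 per PBR codon)
with mostly synonymous variation elsewhere; the diagnostic motif window
147–151 (EDGTV in long, GENE in short alleles) and the main-chain
position 170 (Y, with occasional H/F) are held as class markers.
Randomness derives from a single master seed through per-amplicon
spawned substreams, so any subset of the simulation is reproducible.

What the simulator does *not* emulate: per-base quality and
sequencing-error profiles, index hopping, PCR indels, primer-site
variation, and locus structure (alleles are drawn from one pool rather
than per-locus allele sets). Passing the end-to-end tests therefore
shows the cascade separates the modelled artefact classes from true
alleles under realistic depths — not that it is robust to every noise
mode of a real run.

## Problem sizes and numerical choices

The test suite runs the full cascade at study scale (90 amplicons,
~10⁶ reads in aggregate tallies) and uses down-scaled experiments
(6–20 individuals, depths 6000–9000) for property tests across many
seeds; bootstrap-dependent tests use 50–500 replicates where the default
1000 adds nothing but time. Tolerances on stochastic checks are 3
standard errors unless stated. Ties anywhere (variant order, cluster
assignment, naming, parsimony) break lexicographically to keep every
output deterministic under a fixed seed; reports are written with sorted
keys so reruns are byte-identical.

## Limitations

Raw per-read data from the original experiment are not publicly
deposited, so read-level quantities (calibrated threshold value, mean
depth after filtering, per-amplicon chimera maxima, allele counts from
real birds) can only be exercised on synthetic data here; recomputation
on the deposited allele sequences (GenBank KY351552–KY351598) is wired
into the acceptance suite but needs network access to run. The dN/dS
estimator is the pairwise counting method — no codon-model ML, no
recombination breakpoint detection, no neighbour-nets.
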