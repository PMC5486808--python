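# wadermhc

Genotyping multigene MHC class I from pooled amplicon sequencing, and the
molecular-evolution statistics that follow, for shorebirds and other taxa
where the number of MHC loci is unknown.

When several duplicated MHC loci co-amplify in one PCR, an amplicon
contains reads from an unknown number of true alleles mixed with PCR
artefacts (1–2 bp substitution derivatives of real alleles), PCR chimeras
(prefix/suffix splices of two alleles), and depth noise. `wadermhc`
implements a four-step filtering cascade that turns per-amplicon read
tallies into verified per-individual genotypes:

1. **depth gate** — amplicons below a minimum read depth (default 4000)
   are dropped;
2. **artefact clustering** — a variant 1–2 substitutions from a deeper
   "dominant" variant is merged into it when its depth is ≤ 25% of the
   dominant's; near variants too deep to be artefacts become
   *subdominant* clusters of their own;
3. **frequency threshold** — clusters below a per-amplicon frequency are
   discarded; with no prior on the locus number the threshold is
   calibrated as the best genotype match between technical duplicate
   pairs (exact matches, then mean Jaccard; the smallest optimal grid
   value is kept);
4. **chimera screen** — a cluster whose dominant equals
   `prefix(A, k) + suffix(B, k)` of two deeper equal-length clusters, for
   any breakpoint `k`, is flagged and excluded.

Downstream, called alleles are validated (247-nt *long* vs 244-nt *short*
classes, the short class carrying a 3-bp deletion at alignment codon 147;
translation in the fragment frame with 2-nt incomplete codons at each
end; collapsing of synonymous variants into protein classes; diagnostic
motif annotation; stable `UA*xx` naming) and analysed:

- segregating sites *S*, nucleotide diversity π, mean divergence under
  p-distance and Kimura-2-parameter (optionally gamma-corrected, α = 1)
  models with site-bootstrap SEs;
- Nei–Gojobori *dN/dS* (pathway counting, Jukes–Cantor correction,
  codon-bootstrap SEs, one-tailed Z-test for *dN* > *dS*) partitioned
  over the 12 exon-3 peptide-binding residues (PBR:
  96, 98, 112, 114, 121, 149, 151, 154, 155, 159, 162, 166) versus the
  rest — *dN/dS* > 1 at the PBR is the classic signature of
  pathogen-driven balancing selection;
- per-site selection by a SLAC-style counting test: K2P distances → NJ
  tree → parsimony ancestral codons → per-site binomial test of the
  observed synonymous fraction at *P* = 0.1.

A synthetic-data module simulates the whole experiment (allele pool with
nonsynonymous polymorphism concentrated at the PBR, 1–4 loci per
individual, negative-binomial depths, amplification bias, artefacts,
chimeras, technical duplicates) with exhaustive per-read truth
bookkeeping, so every stage is testable end to end without any
sequencing data.

## Worked example

`examples/simulate_and_call.py` simulates 12 individuals (3 technical
duplicate pairs, mean depth 8000, default noise) and runs the cascade
with automatic calibration:

```
simulated 15 amplicons, mean depth 8446
calibrated frequency threshold: 0.5%
duplicate-pair concordance:     100%
exact genotype recovery:        12/12 individuals
```

The threshold is the smallest grid value at which every duplicate pair
calls an identical allele set; 100% concordance together with exact
recovery means every planted artefact fell below the threshold and every
true allele stayed above it. The other scripts in `examples/` cover
allele validation, the diversity/dN/dS table and per-site selection —
`examples/diversity_stats.py`, for instance, prints a PBR dN/dS of 4.356
against 0.109 outside the PBR for a pool generated with strong
nonsynonymous excess at the peptide-binding residues, and
`examples/site_selection.py` recovers positively selected sites only at
PBR positions.

A thin CLI wraps the same functions: `wadermhc simulate`, `call`,
`validate`, `diversity`, `selection`, `run-all` (see `--help`).

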