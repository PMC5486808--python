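"""Alignment coordinate frame for MHC class I exon 3.

All positions in this package are 1-based amino-acid positions in the
full-protein alignment frame whose first residue is the first residue of
the alpha-1 domain.  The MiSeq exon-3 fragment covers positions 93-173:
the amplified fragment is 247 nt (or 244 nt for alleles carrying a 3-bp
deletion), with 2 nt of incomplete codon at each end, leaving 81 (or 80)
complete codons.
"""

from __future__ import annotations

#: first complete codon of the MiSeq exon-3 fragment, alignment frame
EXON3_FIRST_POSITION = 93

#: number of complete codons in a full-length (247 nt) fragment
EXON3_N_CODONS = 81

#: last covered alignment position
EXON3_LAST_POSITION = EXON3_FIRST_POSITION + EXON3_N_CODONS - 1  # 173

#: alignment position of the codon deleted in short (244 nt) alleles
DELETION_POSITION = 147

#: incomplete-codon overhang at each end of the amplified fragment (nt)
FRAME_OFFSET = 2

#: fragment lengths defining the two allele length classes
LONG_LENGTH = 247
SHORT_LENGTH = 244

#: the 12 exon-3 peptide-binding residues used for the dN/dS partition
PBR_EXON3_DNDS = frozenset({96, 98, 112, 114, 121, 149, 151, 154, 155, 159, 162, 166})

#: the full exon-3 PBR set (includes peptide main-chain-adjacent sites)
PBR_EXON3_FULL = frozenset(
    {96, 98, 112, 114, 121, 141, 144, 145, 149, 151, 154, 155, 158, 159, 162, 166, 170}
)

#: the exon-2 (alpha-1) PBR set, for completeness of the mask vocabulary
PBR_EXON2 = frozenset(
    {5, 7, 9, 24, 25, 34, 43, 58, 62, 65, 66, 68, 69, 72, 73, 75, 76, 79, 80, 83}
)

#: peptide main-chain consensus residues that fall inside the fragment and
#: are assignable to an alignment position; position 170 is tyrosine in the
#: consensus, replaced by H or F in a minority of alleles.
MAIN_CHAIN_EXON3 = {170: "Y"}

#: motif windows used in allele validation (long vs short diagnostic motifs)
MOTIF_EDGTV_SPAN = (147, 151)  # long alleles
MOTIF_GENE_SPAN = (148, 151)  # short alleles


def position_to_codon_index(position: int, first_position: int = EXON3_FIRST_POSITION) -> int:
    """Map a 1-based alignment amino-acid position to a 0-based codon column."""
    idx = position - first_position
    if idx < 0:
        raise ValueError(f"position {position} precedes the covered frame (first {first_position})")
    return idx


def codon_index_to_position(index: int, first_position: int = EXON3_FIRST_POSITION) -> int:
    """Inverse of :func:`position_to_codon_index`."""
    return first_position + index


#: 0-based nt span (within the 247-nt fragment) of the deletion codon
DELETION_NT_START = FRAME_OFFSET + (DELETION_POSITION - EXON3_FIRST_POSITION) * 3  # 164
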