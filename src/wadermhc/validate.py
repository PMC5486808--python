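"""Validation and annotation of called exon-3 alleles.

Alleles come in two length classes: long (247 nt) and short (244 nt,
carrying a 3-bp deletion at alignment codon 147).  The amplified fragment
starts and ends mid-codon, so translation trims 2 nt at each end, giving
81 (long) or 80 (short) residues spanning alignment positions 93-173.
Nucleotide alleles translating to the same protein are collapsed into
protein classes; diagnostic motifs (EDGTV at 147-151 in long alleles,
GENE at 148-151 in short ones) and the main-chain tyrosine at 170 are
annotated.  New alleles receive stable names in the Klein-style
``UA*xx`` series.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .codon import split_codons, translate_codon
from .frame import (
    DELETION_NT_START,
    DELETION_POSITION,
    EXON3_FIRST_POSITION,
    FRAME_OFFSET,
    LONG_LENGTH,
    MAIN_CHAIN_EXON3,
    MOTIF_EDGTV_SPAN,
    MOTIF_GENE_SPAN,
    SHORT_LENGTH,
)
from .io import SequenceRecord


class ValidationError(ValueError):
    pass


class RegistryError(ValueError):
    pass


@dataclass
class MotifReport:
    residue_170: str | None
    has_gene_148_151: bool
    has_edgtv_147_151: bool
    main_chain_deviations: list[tuple[int, str, str]]  # (position, expected, found)


@dataclass
class AlleleCall:
    name: str
    sequence: str
    length_class: str  # "long" | "short"
    protein: str | None  # None when translation hit an internal stop
    protein_class_id: int | None = None
    functional: bool = True
    motifs: MotifReport | None = None
    rejection_reason: str | None = None


def classify_length(sequence: str) -> str:
    """'long' for 247 nt, 'short' for 244 nt; anything else is rejected."""
    if len(sequence) == LONG_LENGTH:
        return "long"
    if len(sequence) == SHORT_LENGTH:
        return "short"
    raise ValidationError(
        f"sequence length {len(sequence)} is neither {LONG_LENGTH} nor {SHORT_LENGTH} nt"
    )


def translate_exon3(sequence: str, frame_offset: int = FRAME_OFFSET) -> str:
    """Translate the fragment after trimming the incomplete-codon overhangs.

    Raises :class:`ValidationError` on an internal stop codon (the allele
    is then flagged non-functional, not silently dropped).
    """
    core = sequence[frame_offset: len(sequence) - frame_offset]
    if len(core) % 3:
        raise ValidationError(
            f"trimmed length {len(core)} is not a whole number of codons"
        )
    protein = "".join(translate_codon(c) for c in split_codons(core))
    if "*" in protein:
        raise ValidationError(
            f"internal stop codon at residue {protein.index('*') + 1}"
        )
    return protein


def align_exon3(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Anchor 244/247-nt fragments into one 247-column alignment.

    Long sequences pass through; short sequences get the 3-bp deletion gap
    at alignment codon 147 (fragment coordinates ``DELETION_NT_START``).
    Off-length sequences raise.
    """
    out = []
    for r in records:
        cls = classify_length(r.sequence)
        if cls == "long":
            out.append(r)
        else:
            s = r.sequence
            out.append(SequenceRecord(
                r.id,
                s[:DELETION_NT_START] + "---" + s[DELETION_NT_START:],
                r.description,
            ))
    return out


def _position_to_index(position: int, length_class: str) -> int | None:
    """Residue index (0-based, unaligned protein) of an alignment position."""
    idx = position - EXON3_FIRST_POSITION
    if idx < 0:
        return None
    if length_class == "short":
        if position == DELETION_POSITION:
            return None
        if position > DELETION_POSITION:
            idx -= 1
    return idx


def annotate_motifs(protein: str, length_class: str,
                    main_chain: dict[int, str] | None = None) -> MotifReport:
    """Motif and conserved-site annotation of one translated allele."""
    main_chain = MAIN_CHAIN_EXON3 if main_chain is None else main_chain

    def residue(position: int) -> str | None:
        idx = _position_to_index(position, length_class)
        if idx is None or idx >= len(protein):
            return None
        return protein[idx]

    def window(span: tuple[int, int]) -> str:
        return "".join(residue(p) or "-" for p in range(span[0], span[1] + 1))

    deviations = [
        (pos, exp, found)
        for pos, exp in sorted(main_chain.items())
        if (found := residue(pos)) is not None and found != exp
    ]
    return MotifReport(
        residue_170=residue(170),
        has_gene_148_151=(length_class == "short" and window(MOTIF_GENE_SPAN) == "GENE"),
        has_edgtv_147_151=(length_class == "long" and window(MOTIF_EDGTV_SPAN) == "EDGTV"),
        main_chain_deviations=deviations,
    )


def collapse_proteins(calls: list[AlleleCall]) -> dict[int, list[AlleleCall]]:
    """Partition alleles into identical-protein classes.

    Class ids are assigned in order of first appearance; non-functional
    alleles (no protein) are excluded from classes.
    """
    classes: dict[str, int] = {}
    members: dict[int, list[AlleleCall]] = {}
    for call in calls:
        if call.protein is None:
            continue
        cid = classes.setdefault(call.protein, len(classes) + 1)
        call.protein_class_id = cid
        members.setdefault(cid, []).append(call)
    return members


_NAME_RE = re.compile(r"\*(\d+)$")


def assign_names(
    sequences: list[str],
    registry: dict[str, str] | None = None,
    prefix: str = "UA",
) -> dict[str, str]:
    """Stable, deterministic allele naming (``UA*01`` style).

    ``sequences`` must already be in canonical order (depth-ranked, ties
    lexicographic).  Sequences present in ``registry`` keep their names;
    new sequences get the next free number, zero-padded to two digits.
    """
    registry = dict(registry or {})
    names = list(registry.values())
    if len(set(names)) != len(names):
        raise RegistryError("registry maps distinct sequences to the same name")
    used = set()
    for name in names:
        m = _NAME_RE.search(name)
        if m:
            used.add(int(m.group(1)))
    nxt = 1
    out: dict[str, str] = {}
    for seq in sequences:
        if seq in registry:
            out[seq] = registry[seq]
            continue
        while nxt in used:
            nxt += 1
        used.add(nxt)
        out[seq] = f"{prefix}*{nxt:02d}"
    return out


def validate_alleles(
    sequences_in_order: list[str],
    registry: dict[str, str] | None = None,
    prefix: str = "UA",
) -> list[AlleleCall]:
    """classify -> translate -> name -> annotate for a canonical-order
    allele list; protein classes are assigned across the whole set."""
    names = assign_names(sequences_in_order, registry, prefix)
    calls = []
    for seq in sequences_in_order:
        name = names[seq]
        try:
            cls = classify_length(seq)
        except ValidationError as exc:
            calls.append(AlleleCall(name, seq, "rejected", None,
                                    functional=False, rejection_reason=str(exc)))
            continue
        try:
            protein = translate_exon3(seq)
        except ValidationError as exc:
            calls.append(AlleleCall(name, seq, cls, None,
                                    functional=False, rejection_reason=str(exc)))
            continue
        call = AlleleCall(name, seq, cls, protein)
        call.motifs = annotate_motifs(protein, cls)
        calls.append(call)
    collapse_proteins(calls)
    return calls
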