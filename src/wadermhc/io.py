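"""External representations: FASTA/FASTQ reads, sample sheets, genotype
tables, alignments and Newick trees.

The pipeline's native interchange is FASTA + TSV.  FASTQ is accepted on
input only (qualities are ignored).  All writers are idempotent under
re-read.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger(__name__)

_NT_ALPHABET = set("ACGTN-")


class FormatError(ValueError):
    """Malformed input file (names the offending record)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence; nucleotide records are upper-case A/C/G/T/N plus '-'."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class SampleSheetRow:
    amplicon_id: str
    individual_id: str
    duplicate_group: str  # empty string when the amplicon is unpaired
    reads_path: Path


@dataclass
class SampleSheet:
    """Amplicon-to-individual map with technical-duplicate pairing."""

    rows: list[SampleSheetRow]

    def __post_init__(self) -> None:
        ids = [r.amplicon_id for r in self.rows]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise FormatError(f"duplicate amplicon_ids in sample sheet: {dup}")
        groups = Counter(r.duplicate_group for r in self.rows if r.duplicate_group)
        bad = {g: c for g, c in groups.items() if c != 2}
        if bad:
            raise FormatError(f"duplicate_group values not occurring exactly twice: {bad}")
        missing = [str(r.reads_path) for r in self.rows if not Path(r.reads_path).exists()]
        if missing:
            raise FileNotFoundError(f"reads files not found: {missing}")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class ReadVariant:
    """One distinct read string within an amplicon, with its read depth."""

    sequence: str
    depth: int


@dataclass
class Amplicon:
    """Per-sample read tallies, variants sorted by depth (ties lexicographic)."""

    amplicon_id: str
    individual_id: str
    duplicate_group: str
    variants: list[ReadVariant] = field(default_factory=list)

    @property
    def total_depth(self) -> int:
        return sum(v.depth for v in self.variants)


@dataclass
class AmpliconSet:
    amplicons: list[Amplicon]

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def by_id(self) -> dict[str, Amplicon]:
        return {a.amplicon_id: a for a in self.amplicons}

    def duplicate_pairs(self) -> dict[str, tuple[Amplicon, Amplicon]]:
        """Map duplicate_group -> the pair of amplicons, in amplicon_id order."""
        groups: dict[str, list[Amplicon]] = {}
        for a in self.amplicons:
            if a.duplicate_group:
                groups.setdefault(a.duplicate_group, []).append(a)
        return {
            g: tuple(sorted(pair, key=lambda a: a.amplicon_id))  # type: ignore[misc]
            for g, pair in groups.items()
            if len(pair) == 2
        }


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into upper-cased records, in file order."""
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, seq, rec.description))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    path = Path(path)
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def _iter_reads(path: Path) -> Iterable[str]:
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield str(rec.seq).upper()


def tally_reads(reads: Iterable[str]) -> tuple[list[ReadVariant], int]:
    """Collapse identical read strings into depth-sorted variants.

    Reads containing N cannot be alleles and are excluded from the tallies;
    the number excluded is returned alongside.
    """
    counts: Counter[str] = Counter()
    n_dropped = 0
    for seq in reads:
        if "N" in seq:
            n_dropped += 1
            continue
        counts[seq] += 1
    variants = [
        ReadVariant(s, d)
        for s, d in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return variants, n_dropped


def read_amplicons(sheet: SampleSheet) -> AmpliconSet:
    """Load and tally per-amplicon reads according to a sample sheet."""
    amplicons = []
    for row in sheet:
        variants, n_dropped = tally_reads(_iter_reads(Path(row.reads_path)))
        if n_dropped:
            log.info("amplicon %s: %d reads containing N excluded", row.amplicon_id, n_dropped)
        amplicons.append(
            Amplicon(row.amplicon_id, row.individual_id, row.duplicate_group, variants)
        )
    return AmpliconSet(amplicons)


# ---------------------------------------------------------------------------
# sample sheet TSV
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ["amplicon_id", "individual_id", "duplicate_group", "reads_path"]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    base = path.parent
    rows = [
        SampleSheetRow(
            r.amplicon_id,
            r.individual_id,
            r.duplicate_group,
            (base / r.reads_path) if not Path(r.reads_path).is_absolute() else Path(r.reads_path),
        )
        for r in df.itertuples()
    ]
    return SampleSheet(rows)


def write_sample_sheet(sheet: SampleSheet | Iterable[SampleSheetRow],
                       path: str | Path) -> None:
    """Write sheet rows as TSV; relative reads_paths are interpreted
    relative to the sheet's directory on re-read."""
    df = pd.DataFrame(
        [
            (r.amplicon_id, r.individual_id, r.duplicate_group, str(r.reads_path))
            for r in sheet
        ],
        columns=SHEET_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def write_genotype_table(genotypes: dict[str, set[str]], path: str | Path) -> None:
    """Write a long-format genotype TSV plus a wide presence/absence matrix.

    ``genotypes`` maps individual_id -> set of allele names.  The long table
    goes to ``path``; the matrix to ``path`` with a ``.matrix.tsv`` suffix.
    """
    path = Path(path)
    rows = [
        (ind, allele)
        for ind in sorted(genotypes)
        for allele in sorted(genotypes[ind])
    ]
    pd.DataFrame(rows, columns=["individual_id", "allele"]).to_csv(path, sep="\t", index=False)

    alleles = sorted({a for s in genotypes.values() for a in s})
    matrix = pd.DataFrame(
        [[int(a in genotypes[ind]) for a in alleles] for ind in sorted(genotypes)],
        index=sorted(genotypes),
        columns=alleles,
    )
    matrix.index.name = "individual_id"
    matrix.to_csv(path.with_suffix(".matrix.tsv"), sep="\t")


def read_genotype_table(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(r.individual_id, set()).add(r.allele)
    return out


# ---------------------------------------------------------------------------
# alignments and trees
# ---------------------------------------------------------------------------

class AlignmentError(ValueError):
    pass


def read_alignment(path: str | Path) -> list[SequenceRecord]:
    """Read an aligned FASTA; all sequences must have equal aligned length."""
    records = read_fasta(path)
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        raise AlignmentError(f"{path}: unequal aligned lengths {sorted(lengths)}")
    return records


def write_newick(tree, path: str | Path) -> None:
    """Write a scikit-bio TreeNode with branch lengths and bootstrap labels."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")


# ---------------------------------------------------------------------------
# GenBank (online only; used for recomputation against deposited alleles)
# ---------------------------------------------------------------------------

def fetch_genbank_alleles(accessions: Sequence[str], email: str = "wadermhc@example.org",
                          timeout: float = 30.0) -> list[SequenceRecord]:
    """Fetch nucleotide records from GenBank by accession (requires network)."""
    import socket

    from Bio import Entrez

    Entrez.email = email
    old = socket.getdefaulttimeout()
    socket.setdefaulttimeout(timeout)
    try:
        handle = Entrez.efetch(
            db="nuccore", id=",".join(accessions), rettype="fasta", retmode="text"
        )
        records = [
            SequenceRecord(rec.id.split(".")[0], str(rec.seq).upper(), rec.description)
            for rec in SeqIO.parse(handle, "fasta")
        ]
    finally:
        socket.setdefaulttimeout(old)
    if len(records) != len(accessions):
        raise FormatError(
            f"expected {len(accessions)} records, GenBank returned {len(records)}"
        )
    return records


def accession_range(first: str, last: str) -> list[str]:
    """Expand an accession range like KY351556-KY351598 into a list."""
    prefix = first.rstrip("0123456789")
    if last.rstrip("0123456789") != prefix:
        raise ValueError(f"accession prefixes differ: {first}, {last}")
    a, b = int(first[len(prefix):]), int(last[len(prefix):])
    width = len(first) - len(prefix)
    return [f"{prefix}{i:0{width}d}" for i in range(a, b + 1)]
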