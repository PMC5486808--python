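"""Synthetic amplicon data with the statistical structure the genotyping
cascade assumes.

The generator emulates a pooled MHC class I exon-3 amplicon experiment:
a pool of 247-bp alleles plus 244-bp alleles carrying a 3-bp deletion at
alignment codon 147, elevated nonsynonymous polymorphism at the
peptide-binding residues, 1-4 loci per individual, per-amplicon read
depths in the thousands (negative-binomial), per-allele amplification
bias, PCR single-base artefacts 1-2 bp from their parent, PCR chimeras
spliced from equal-length parents, and technical duplicate amplicons that
are independent redraws from the same genotype.  Every simulated read has
exactly one recorded origin, so downstream stages can be scored exactly.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import frame
from .io import (
    Amplicon,
    AmpliconSet,
    ReadVariant,
    SampleSheet,
    SampleSheetRow,
    SequenceRecord,
    write_fasta,
    write_sample_sheet,
)

log = logging.getLogger(__name__)

_BASES = "ACGT"

# canonical codon per amino acid (no stops), used for back-translation
_CODON_FOR_AA = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC", "G": "GGC",
    "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCC", "Q": "CAG", "R": "AGG", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAC",
}

# synonymous alternatives reachable from the canonical codon
_SYN_ALTERNATIVES = {
    "A": ["GCT", "GCA", "GCG"], "C": ["TGT"], "D": ["GAT"], "E": ["GAA"],
    "F": ["TTT"], "G": ["GGT", "GGA", "GGG"], "H": ["CAT"], "I": ["ATT", "ATA"],
    "K": ["AAA"], "L": ["CTC", "CTT", "CTA"], "M": [], "N": ["AAT"],
    "P": ["CCT", "CCA", "CCG"], "Q": ["CAA"], "R": ["AGA", "CGG"],
    "S": ["TCC", "AGT"], "T": ["ACT", "ACA", "ACG"], "V": ["GTC", "GTT"],
    "W": [], "Y": ["TAT"],
}

_COMMON_AA = "ADEFGHIKLNQRSTVWY"  # residue pool for base/backbone positions
_PBR_AA = "ADEFHIKLNQRSTVWY"  # replacement pool at peptide-binding residues


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic amplicon experiment."""

    n_long_alleles: int = 38
    n_short_alleles: int = 9
    allele_length_long: int = frame.LONG_LENGTH
    deletion_length: int = 3
    deletion_codon_position: int = frame.DELETION_POSITION
    n_individuals: int = 84
    loci_range: tuple[int, int] = (1, 4)
    depth_mean: float = 11000.0
    depth_dispersion: float = 20.0
    pcr_error_rate: float = 0.02
    chimera_rate: float = 0.003
    amplification_bias_sd: float = 0.3
    n_duplicate_pairs: int = 6
    pbr_substitution_rate: float = 0.5
    nonpbr_synonymous_rate: float = 0.10
    nonpbr_nonsynonymous_rate: float = 0.015
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_long_alleles, self.n_short_alleles, self.n_individuals,
               self.n_duplicate_pairs) < 0:
            raise ValueError("counts must be >= 0")
        for rate in (self.pcr_error_rate, self.chimera_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mean and depth_dispersion must be positive")
        lo, hi = self.loci_range
        if not (1 <= lo <= hi <= 4):
            raise ValueError("loci_range must lie within [1, 4]")
        if self.n_duplicate_pairs > self.n_individuals:
            raise ValueError("more duplicate pairs than individuals")


class GenerationError(RuntimeError):
    """The requested pool cannot be realized (e.g. not enough sequence space)."""


@dataclass
class TruthTable:
    """Simulator bookkeeping: alleles, genotypes, and per-read origins.

    Read origins are encoded as strings:
    ``allele:<id>``, ``artefact:<parent>:<n_edits>``,
    ``chimera:<parentA>:<parentB>:<breakpoint>``.
    """

    alleles: list[SequenceRecord]
    pbr_mask: frozenset[int]
    genotypes: dict[str, dict[str, int]] = field(default_factory=dict)
    read_origins: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)

    @property
    def allele_seq(self) -> dict[str, str]:
        return {a.id: a.sequence for a in self.alleles}

    def genotype_sequences(self, individual_id: str) -> set[str]:
        seqs = self.allele_seq
        return {seqs[a] for a in self.genotypes[individual_id]}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alleles": [(a.id, a.sequence) for a in self.alleles],
            "pbr_mask": sorted(self.pbr_mask),
            "genotypes": {k: dict(v) for k, v in self.genotypes.items()},
            "read_origins": self.read_origins,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


# ---------------------------------------------------------------------------
# allele pool
# ---------------------------------------------------------------------------

def _base_protein(rng: np.random.Generator) -> list[str]:
    """Backbone 81-residue protein (alignment positions 93-173)."""
    aa = [str(c) for c in rng.choice(list(_COMMON_AA), size=frame.EXON3_N_CODONS)]
    i0 = frame.position_to_codon_index
    # long-allele diagnostic motif EDGTV at 147-151
    for pos, res in zip(range(147, 152), "EDGTV"):
        aa[i0(pos)] = res
    # main-chain tyrosine at 170
    aa[i0(170)] = "Y"
    return aa


def _encode(aa_codons: list[tuple[str, str | None]]) -> str:
    """Nucleotide core from (residue, codon-override) pairs."""
    return "".join(c if c is not None else _CODON_FOR_AA[a] for a, c in aa_codons)


def generate_allele_pool(cfg: SimulationConfig
                         ) -> tuple[list[SequenceRecord], frozenset[int]]:
    """Generate the allele pool and the PBR mask used to concentrate
    nonsynonymous polymorphism.

    Returns ``cfg.n_long_alleles`` sequences of 247 nt and
    ``cfg.n_short_alleles`` of 244 nt, all translatable without stops in
    the declared frame (2-nt overhang at each end) and pairwise distinct.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    base = _base_protein(rng)
    mask = frame.PBR_EXON3_DNDS
    pbr_idx = sorted(frame.position_to_codon_index(p) for p in mask)
    pos170 = frame.position_to_codon_index(170)
    del_idx = frame.position_to_codon_index(cfg.deletion_codon_position)

    # the diagnostic motif window (147-151) stays an invariant class marker,
    # even where it overlaps the PBR mask (positions 149, 151)
    motif_idx = set(range(del_idx, del_idx + 5))

    flank5, flank3 = "GT", "CA"  # incomplete-codon overhangs
    seen: set[str] = set()
    records: list[SequenceRecord] = []

    def make_allele(short: bool) -> str:
        aa = list(base)
        codon_override: dict[int, str] = {}
        for i in pbr_idx:
            if i in motif_idx:
                continue
            if rng.random() < cfg.pbr_substitution_rate:
                choices = [c for c in _PBR_AA if c != aa[i]]
                aa[i] = str(rng.choice(choices))
        if rng.random() < 0.2:
            aa[pos170] = str(rng.choice(["H", "F"]))
        for i in range(len(aa)):
            if i in pbr_idx:
                continue
            r = rng.random()
            alts = _SYN_ALTERNATIVES[aa[i]]
            if r < cfg.nonpbr_synonymous_rate and alts:
                codon_override[i] = str(rng.choice(alts))
            elif r < cfg.nonpbr_synonymous_rate + cfg.nonpbr_nonsynonymous_rate:
                if i != pos170 and i not in motif_idx:
                    aa[i] = str(rng.choice([c for c in _COMMON_AA if c != aa[i]]))
        if short:
            # delete codon 147 and install the short-allele GENE motif at 148-151
            for off, res in zip(range(1, 5), "GENE"):
                aa[del_idx + off] = res
                codon_override.pop(del_idx + off, None)
            pairs = [
                (aa[i], codon_override.get(i))
                for i in range(len(aa))
                if i != del_idx
            ]
        else:
            pairs = [(aa[i], codon_override.get(i)) for i in range(len(aa))]
        return flank5 + _encode(pairs) + flank3

    for n, short, length in (
        (cfg.n_long_alleles, False, cfg.allele_length_long),
        (cfg.n_short_alleles, True, cfg.allele_length_long - cfg.deletion_length),
    ):
        made = 0
        attempts = 0
        while made < n:
            attempts += 1
            if attempts > 200 * max(n, 1):
                raise GenerationError(
                    f"could not realize {n} distinct "
                    f"{'short' if short else 'long'} alleles"
                )
            seq = make_allele(short)
            assert len(seq) == length
            if seq in seen:
                continue
            seen.add(seq)
            made += 1
            records.append(SequenceRecord(f"allele{len(records) + 1:02d}", seq))
    return records, mask


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(pool: list[SequenceRecord], cfg: SimulationConfig) -> TruthTable:
    """Draw per-individual genotypes: a locus count in ``loci_range``, then
    two allele draws per locus with replacement from the pool."""
    cfg.validate()
    if not pool:
        raise ValueError("empty allele pool")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    truth = TruthTable(alleles=list(pool), pbr_mask=frame.PBR_EXON3_DNDS)
    ids = [a.id for a in pool]
    lo, hi = cfg.loci_range
    for i in range(cfg.n_individuals):
        ind = f"ind{i + 1:03d}"
        loci = int(rng.integers(lo, hi + 1))
        draws = rng.choice(ids, size=2 * loci, replace=True)
        truth.genotypes[ind] = dict(Counter(str(a) for a in draws))
    return truth


# ---------------------------------------------------------------------------
# amplicons
# ---------------------------------------------------------------------------

def _mutate(seq: str, rng: np.random.Generator, n_sub: int) -> str:
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for p in positions:
        chars[p] = str(rng.choice([b for b in _BASES if b != chars[p]]))
    return "".join(chars)


def _amplicon_plan(cfg: SimulationConfig) -> list[tuple[str, str, str]]:
    """(amplicon_id, individual_id, duplicate_group) rows; the first
    ``n_duplicate_pairs`` individuals get a second, independent amplicon."""
    rows = []
    for i in range(cfg.n_individuals):
        ind = f"ind{i + 1:03d}"
        group = ind if i < cfg.n_duplicate_pairs else ""
        rows.append((f"{ind}-a", ind, group))
        if group:
            rows.append((f"{ind}-b", ind, group))
    return rows


def simulate_amplicons(truth: TruthTable, cfg: SimulationConfig) -> AmpliconSet:
    """Simulate per-amplicon read tallies and record every read's origin."""
    cfg.validate()
    plan = _amplicon_plan(cfg)
    master = np.random.SeedSequence([cfg.seed, 2])
    streams = master.spawn(len(plan))
    seqs = truth.allele_seq
    amplicons = []
    for (amp_id, ind, group), stream in zip(plan, streams):
        rng = np.random.default_rng(stream)
        genotype = truth.genotypes[ind]
        allele_ids = sorted(genotype)
        copies = np.array([genotype[a] for a in allele_ids], dtype=float)
        bias = rng.lognormal(mean=0.0, sigma=cfg.amplification_bias_sd,
                             size=len(allele_ids))
        weights = copies * bias
        weights /= weights.sum()
        r = cfg.depth_dispersion
        depth = int(rng.negative_binomial(r, r / (r + cfg.depth_mean)))
        counts = rng.multinomial(depth, weights)

        tallies: Counter[str] = Counter()
        origins: dict[str, Counter[str]] = {}

        def add(seq: str, origin: str, n: int = 1) -> None:
            tallies[seq] += n
            origins.setdefault(seq, Counter())[origin] += n

        e, c = cfg.pcr_error_rate, cfg.chimera_rate
        for aid, n_reads in zip(allele_ids, counts):
            if n_reads == 0:
                continue
            parent = seqs[aid]
            n_clean, n_err, n_chi = rng.multinomial(
                n_reads, [1.0 - e - c, e, c]
            )
            if n_clean:
                add(parent, f"allele:{aid}", int(n_clean))
            for _ in range(int(n_err)):
                n_sub = 1 if rng.random() < 0.75 else 2
                add(_mutate(parent, rng, n_sub), f"artefact:{aid}:{n_sub}")
            partners = [
                b for b in allele_ids
                if b != aid and len(seqs[b]) == len(parent)
            ]
            for _ in range(int(n_chi)):
                if not partners:
                    log.info(
                        "amplicon %s: chimera requested for %s without an "
                        "equal-length partner; emitting an error read", amp_id, aid,
                    )
                    add(_mutate(parent, rng, 1), f"artefact:{aid}:1")
                    continue
                pb = str(rng.choice(partners))
                k = int(rng.integers(1, len(parent)))
                add(parent[:k] + seqs[pb][k:], f"chimera:{aid}:{pb}:{k}")

        variants = [
            ReadVariant(s, d)
            for s, d in sorted(tallies.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        truth.read_origins[amp_id] = {
            s: dict(cnt) for s, cnt in origins.items()
        }
        amplicons.append(Amplicon(amp_id, ind, group, variants))
    return AmpliconSet(amplicons)


def simulate(cfg: SimulationConfig) -> tuple[AmpliconSet, TruthTable]:
    """Pool -> genotypes -> amplicons, fully determined by ``cfg.seed``."""
    pool, _ = generate_allele_pool(cfg)
    truth = simulate_genotypes(pool, cfg)
    amplicons = simulate_amplicons(truth, cfg)
    return amplicons, truth


# ---------------------------------------------------------------------------
# on-disk simulation (FASTA reads + sample sheet + truth table)
# ---------------------------------------------------------------------------

def write_simulation(amplicons: AmpliconSet, truth: TruthTable,
                     outdir: str | Path, cfg: SimulationConfig | None = None
                     ) -> Path:
    """Write per-amplicon read FASTAs, the sample sheet, allele FASTA and
    truth table under ``outdir``; returns the sample-sheet path."""
    outdir = Path(outdir)
    reads_dir = outdir / "reads"
    reads_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for amp in amplicons:
        path = reads_dir / f"{amp.amplicon_id}.fasta"
        records = []
        i = 0
        for v in amp.variants:
            for _ in range(v.depth):
                i += 1
                records.append(SequenceRecord(f"{amp.amplicon_id}.r{i:06d}", v.sequence))
        write_fasta(records, path)
        # paths in the TSV are relative to the sheet's own directory
        rows.append(SampleSheetRow(amp.amplicon_id, amp.individual_id,
                                   amp.duplicate_group,
                                   path.relative_to(outdir)))
    sheet_path = outdir / "sample_sheet.tsv"
    write_sample_sheet(rows, sheet_path)
    write_fasta(truth.alleles, outdir / "true_alleles.fasta")
    truth.to_json(outdir / "truth.json")
    if cfg is not None:
        (outdir / "sim_config.json").write_text(
            json.dumps(asdict(cfg), sort_keys=True, indent=1)
        )
    return sheet_path
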