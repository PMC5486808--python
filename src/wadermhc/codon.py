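"""Nei-Gojobori codon counting: synonymous/nonsynonymous potential sites
and pathway-averaged difference counts, with Jukes-Cantor correction.

All counting uses the standard genetic code.  Substitutions that would
create a stop codon are counted as nonsynonymous (a change to a stop is
never silent), and per-codon potential sites are normalized so that
synonymous + nonsynonymous sites equal 3 per codon.  Multi-step codon
differences are averaged over all mutational pathways, including those
passing through stop codons (counted as nonsynonymous steps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"

GAP_CODON = "---"


def is_stop(codon: str) -> bool:
    return codon in _STOPS


@lru_cache(maxsize=None)
def translate_codon(codon: str) -> str:
    """Single-codon translation; '*' for stops, '-' for the gap codon."""
    if codon == GAP_CODON:
        return "-"
    if codon in _STOPS:
        return "*"
    return _TABLE.forward_table[codon]


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """Potential (synonymous, nonsynonymous) sites of one codon.

    Normalized so the two components sum to 3.
    """
    if codon == GAP_CODON or codon in _STOPS:
        raise ValueError(f"cannot count sites of codon {codon!r}")
    aa = translate_codon(codon)
    syn = nonsyn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _STOPS or translate_codon(alt) != aa:
                nonsyn += 1.0
            else:
                syn += 1.0
    norm = (syn + nonsyn) / 3.0
    return syn / norm, nonsyn / norm


def _step_type(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) classification of a single-step codon change."""
    a1 = translate_codon(c1) if c1 not in _STOPS else "*"
    a2 = translate_codon(c2) if c2 not in _STOPS else "*"
    return (1.0, 0.0) if a1 == a2 else (0.0, 1.0)


@lru_cache(maxsize=None)
def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons."""
    if c1 == c2:
        return 0.0, 0.0
    diff = [i for i in range(3) if c1[i] != c2[i]]
    syn = nonsyn = 0.0
    n_paths = math.factorial(len(diff))
    for order in permutations(diff):
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            s, n = _step_type(cur, nxt)
            syn += s / n_paths
            nonsyn += n / n_paths
            cur = nxt
    return syn, nonsyn


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor correction of a proportion of differences."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise ValueError(f"proportion {p} not correctable (>= 3/4)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class PairCounts:
    """Raw Nei-Gojobori counts for one sequence pair."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int  # codons compared after pairwise deletion

    @property
    def ps(self) -> float:
        return self.syn_diffs / self.syn_sites if self.syn_sites else 0.0

    @property
    def pn(self) -> float:
        return self.nonsyn_diffs / self.nonsyn_sites if self.nonsyn_sites else 0.0


def _usable(codon: str) -> bool:
    return (
        len(codon) == 3
        and "-" not in codon
        and all(b in _BASES for b in codon)
        and codon not in _STOPS
    )


def pair_counts(codons1: list[str], codons2: list[str]) -> PairCounts:
    """Nei-Gojobori counts for a pair of codon sequences.

    Codons with gaps, ambiguity or stops in either sequence are excluded
    (pairwise deletion).
    """
    if len(codons1) != len(codons2):
        raise ValueError("codon sequences differ in length")
    S = N = Sd = Nd = 0.0
    used = 0
    for c1, c2 in zip(codons1, codons2):
        if not (_usable(c1) and _usable(c2)):
            continue
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = codon_differences(c1, c2)
        Sd += sd
        Nd += nd
        used += 1
    return PairCounts(S, N, Sd, Nd, used)


def pair_dn_ds(codons1: list[str], codons2: list[str], correct: bool = True
               ) -> tuple[float, float]:
    """(dN, dS) for one pair, Jukes-Cantor corrected by default."""
    c = pair_counts(codons1, codons2)
    if not correct:
        return c.pn, c.ps
    return jukes_cantor(c.pn), jukes_cantor(c.ps)


def split_codons(seq: str, offset: int = 0) -> list[str]:
    """Split an (aligned) nucleotide string into codons after an offset trim.

    Trailing bases that do not fill a codon are discarded.
    """
    trimmed = seq[offset:]
    return [trimmed[i : i + 3] for i in range(0, len(trimmed) - len(trimmed) % 3, 3)]
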