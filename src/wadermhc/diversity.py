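"""Diversity and divergence statistics over aligned allele sets.

Implements segregating sites, nucleotide diversity (pi), pairwise and mean
evolutionary divergence under p-distance and Kimura 2-parameter models
(optionally gamma-rate corrected), and Nei-Gojobori dN/dS over a
PBR/non-PBR codon partition, with site-bootstrap standard errors and a
one-tailed Z-test for positive selection (dN > dS).

Gap columns are handled by pairwise deletion throughout, so the 3-bp
deletion column present in short alleles does not erase information from
long-by-long pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from . import codon as _codon
from .frame import EXON3_FIRST_POSITION, FRAME_OFFSET, PBR_EXON3_DNDS
from .io import SequenceRecord

log = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Codon-indexed alignment in the full-protein coordinate frame.

    ``rows`` maps sequence id -> list of codons (``---`` for the gap codon);
    ``positions[i]`` is the 1-based alignment amino-acid position of codon
    column ``i``.
    """

    rows: dict[str, list[str]]
    positions: list[int]
    dropped_duplicates: dict[str, str] = field(default_factory=dict)

    @property
    def n_codons(self) -> int:
        return len(self.positions)

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def subset(self, positions: set[int]) -> "CodonAlignment":
        idx = [i for i, p in enumerate(self.positions) if p in positions]
        return CodonAlignment(
            {k: [v[i] for i in idx] for k, v in self.rows.items()},
            [self.positions[i] for i in idx],
        )


@dataclass(frozen=True)
class DiversityResult:
    s_nt: int
    s_aa: int
    pi: float
    d_nt: float
    d_nt_se: float
    d_aa: float
    d_aa_se: float
    n_nt: int
    n_aa: int


@dataclass(frozen=True)
class DnDsResult:
    partition: str
    dn: float
    dn_se: float
    ds: float
    ds_se: float
    n: int
    z_p_value: float

    @property
    def ratio(self) -> float:
        """dN/dS; NaN when dS = 0 (undefined)."""
        return self.dn / self.ds if self.ds > 0 else float("nan")


def build_codon_alignment(
    records: list[SequenceRecord],
    offset: int = FRAME_OFFSET,
    first_position: int = EXON3_FIRST_POSITION,
    deduplicate: bool = True,
) -> CodonAlignment:
    """Trim incomplete-codon overhangs and split an aligned set into codons.

    The amplified fragment starts and ends mid-codon; ``offset`` nucleotides
    are trimmed from the start and the remainder is cut into complete
    codons (a partial trailing codon is discarded).  Sequences that become
    identical after trimming are collapsed onto the first-seen id when
    ``deduplicate`` is set, mirroring how incomplete codons reduce the
    usable allele count.
    """
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"unequal aligned lengths: {sorted(lengths)}")
    rows: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    dropped: dict[str, str] = {}
    for r in records:
        codons = _codon.split_codons(r.sequence, offset)
        key = "".join(codons)
        if deduplicate and key in seen:
            dropped[r.id] = seen[key]
            continue
        seen[key] = r.id
        rows[r.id] = codons
    n = len(next(iter(rows.values())))
    positions = [first_position + i for i in range(n)]
    return CodonAlignment(rows, positions, dropped)


def partition_codons(
    aln: CodonAlignment, mask: set[int] | frozenset[int] = PBR_EXON3_DNDS
) -> tuple[CodonAlignment, CodonAlignment]:
    """Split a codon alignment into (PBR, non-PBR) sub-alignments."""
    covered = set(aln.positions)
    outside = sorted(set(mask) - covered)
    if outside:
        raise ValueError(f"mask positions outside the covered frame: {outside}")
    return aln.subset(set(mask)), aln.subset(covered - set(mask))


# ---------------------------------------------------------------------------
# site statistics
# ---------------------------------------------------------------------------

def segregating_sites(sequences: list[str]) -> int:
    """Number of alignment columns with at least two distinct non-gap states."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    if len({len(s) for s in sequences}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    count = 0
    for col in zip(*sequences):
        states = {c for c in col if c != "-"}
        if len(states) >= 2:
            count += 1
    return count


def nucleotide_diversity(sequences: list[str]) -> float:
    """Mean pairwise per-site p-distance (pi), pairwise gap deletion."""
    n = len(sequences)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = _p_distance(sequences[i], sequences[j])
            if d is None:
                log.warning("pair (%d, %d) has no comparable sites; skipped", i, j)
                continue
            total += d
            pairs += 1
    return total / pairs if pairs else 0.0


def _p_distance(a: str, b: str) -> float | None:
    overlap = mismatch = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        overlap += 1
        if x != y:
            mismatch += 1
    return mismatch / overlap if overlap else None


def _ts_tv(a: str, b: str) -> tuple[int, int, int]:
    """(transitions, transversions, overlap) after pairwise gap deletion."""
    ts = tv = overlap = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        overlap += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return ts, tv, overlap


def kimura_2p(P: float, Q: float, gamma_alpha: float | None = None) -> float:
    """Kimura 2-parameter distance from transition/transversion proportions.

    With ``gamma_alpha`` the gamma-rate-corrected form is used (each
    ``-ln x`` term becomes ``a (x^{-1/a} - 1)``).
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError(f"K2P undefined for P={P}, Q={Q}")
    if gamma_alpha is None:
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    a = gamma_alpha
    return (a / 2.0) * (w1 ** (-1.0 / a) - 1.0) + (a / 4.0) * (w2 ** (-1.0 / a) - 1.0)


def pairwise_distance(
    a: str, b: str, model: str = "p", gamma_alpha: float | None = None
) -> float:
    """Distance between two aligned sequences under p or K2P models."""
    if model == "p":
        d = _p_distance(a, b)
        if d is None:
            raise ValueError("no comparable sites after gap deletion")
        return d
    if model == "k2p":
        ts, tv, overlap = _ts_tv(a, b)
        if overlap == 0:
            raise ValueError("no comparable sites after gap deletion")
        return kimura_2p(ts / overlap, tv / overlap, gamma_alpha)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# mean divergence with site-bootstrap SE
# ---------------------------------------------------------------------------

def _pair_site_arrays(sequences: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair, per-column indicator arrays (valid, mismatch, transition)."""
    n = len(sequences)
    L = len(sequences[0])
    arr = np.array([list(s) for s in sequences])
    valid_col = arr != "-"
    pur = np.isin(arr, list("AG"))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    valid = np.empty((len(pairs), L), dtype=bool)
    mismatch = np.empty_like(valid)
    transition = np.empty_like(valid)
    for k, (i, j) in enumerate(pairs):
        v = valid_col[i] & valid_col[j]
        m = v & (arr[i] != arr[j])
        valid[k] = v
        mismatch[k] = m
        transition[k] = m & (pur[i] == pur[j])
    return valid, mismatch, transition


def _mean_d(valid, mismatch, transition, w, model, gamma_alpha):
    overlap = valid @ w
    ok = overlap > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        if model == "p":
            d = (mismatch @ w) / overlap
        else:
            P = (transition @ w) / overlap
            Q = ((mismatch @ w) - (transition @ w)) / overlap
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            bad = (w1 <= 0) | (w2 <= 0)
            w1 = np.where(bad, np.nan, w1)
            w2 = np.where(bad, np.nan, w2)
            if gamma_alpha is None:
                d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
            else:
                a = gamma_alpha
                d = (a / 2.0) * (w1 ** (-1.0 / a) - 1.0) + (a / 4.0) * (
                    w2 ** (-1.0 / a) - 1.0
                )
        d = np.where(ok, d, np.nan)
    return float(np.nanmean(d))


def mean_divergence(
    sequences: list[str],
    model: str = "p",
    gamma_alpha: float | None = None,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mean over all pairs of pairwise distance, with site-bootstrap SE.

    Pairs undefined under the model (K2P domain violations, or no overlap)
    are dropped from the mean of the replicate in which they occur.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    valid, mismatch, transition = _pair_site_arrays(sequences)
    L = valid.shape[1]
    ones = np.ones(L)
    d = _mean_d(valid, mismatch, transition, ones, model, gamma_alpha)
    if bootstrap_reps <= 0:
        return d, 0.0
    rng = np.random.default_rng(seed)
    reps = np.empty(bootstrap_reps)
    for r in range(bootstrap_reps):
        w = rng.multinomial(L, np.full(L, 1.0 / L)).astype(float)
        reps[r] = _mean_d(valid, mismatch, transition, w, model, gamma_alpha)
    return d, float(np.nanstd(reps, ddof=1))


# ---------------------------------------------------------------------------
# Nei-Gojobori dN/dS with codon-bootstrap SE and Z-test
# ---------------------------------------------------------------------------

def _ng_pair_arrays(aln: CodonAlignment):
    """Per-pair, per-codon (S, N, Sd, Nd, usable) arrays."""
    ids = aln.ids
    C = aln.n_codons
    pairs = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    S = np.zeros((len(pairs), C))
    N = np.zeros_like(S)
    Sd = np.zeros_like(S)
    Nd = np.zeros_like(S)
    for k, (i, j) in enumerate(pairs):
        r1, r2 = aln.rows[ids[i]], aln.rows[ids[j]]
        for c in range(C):
            c1, c2 = r1[c], r2[c]
            if not (_codon._usable(c1) and _codon._usable(c2)):
                continue
            s1, n1 = _codon.codon_sites(c1)
            s2, n2 = _codon.codon_sites(c2)
            S[k, c] = (s1 + s2) / 2.0
            N[k, c] = (n1 + n2) / 2.0
            sd, nd = _codon.codon_differences(c1, c2)
            Sd[k, c] = sd
            Nd[k, c] = nd
    return S, N, Sd, Nd


def _ng_means(S, N, Sd, Nd, w, correct=True) -> tuple[float, float]:
    s = S @ w
    n = N @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        ps = np.where(s > 0, (Sd @ w) / s, 0.0)
        pn = np.where(n > 0, (Nd @ w) / n, 0.0)
        if correct:
            ps = np.where(ps < 0.75, -0.75 * np.log(1.0 - 4.0 * ps / 3.0), np.nan)
            pn = np.where(pn < 0.75, -0.75 * np.log(1.0 - 4.0 * pn / 3.0), np.nan)
    bad = np.isnan(ps) | np.isnan(pn)
    if bad.all():
        return float("nan"), float("nan")
    return float(np.mean(pn[~bad])), float(np.mean(ps[~bad]))


def nei_gojobori_dnds(
    aln: CodonAlignment,
    partition: str = "all",
    bootstrap_reps: int = 1000,
    seed: int | None = None,
    correct: bool = True,
) -> DnDsResult:
    """Average pairwise dN and dS with codon-bootstrap SEs and a one-tailed
    Z-test for dN > dS.

    Pairs whose proportion of differences is not Jukes-Cantor correctable
    (>= 3/4) are excluded with a warning.
    """
    if len(aln.rows) < 2:
        raise ValueError("need at least 2 sequences")
    S, N, Sd, Nd = _ng_pair_arrays(aln)
    C = aln.n_codons
    ones = np.ones(C)
    dn, ds = _ng_means(S, N, Sd, Nd, ones, correct)
    if bootstrap_reps <= 0:
        return DnDsResult(partition, dn, 0.0, ds, 0.0, len(aln.rows), float("nan"))
    rng = np.random.default_rng(seed)
    dn_r = np.empty(bootstrap_reps)
    ds_r = np.empty(bootstrap_reps)
    for r in range(bootstrap_reps):
        w = rng.multinomial(C, np.full(C, 1.0 / C)).astype(float)
        dn_r[r], ds_r[r] = _ng_means(S, N, Sd, Nd, w, correct)
    dn_se = float(np.nanstd(dn_r, ddof=1))
    ds_se = float(np.nanstd(ds_r, ddof=1))
    diff_se = float(np.nanstd(dn_r - ds_r, ddof=1))
    if diff_se > 0:
        z = (dn - ds) / diff_se
        p = float(norm.sf(z))
    else:
        p = 1.0 if dn <= ds else 0.0
    return DnDsResult(partition, dn, dn_se, ds, ds_se, len(aln.rows), p)


# ---------------------------------------------------------------------------
# Table-style summary over an allele set
# ---------------------------------------------------------------------------

def translate_alignment(sequences: list[str], offset: int = FRAME_OFFSET) -> list[str]:
    """Aligned amino-acid strings from aligned nucleotides ('-' preserved)."""
    out = []
    for s in sequences:
        codons = _codon.split_codons(s, offset)
        out.append("".join(_codon.translate_codon(c) if "-" not in c else "-" for c in codons))
    return out


def diversity_summary(
    records: list[SequenceRecord],
    mask: set[int] | frozenset[int] = PBR_EXON3_DNDS,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> tuple[DiversityResult, DnDsResult, DnDsResult]:
    """Diversity row plus PBR / non-PBR dN/dS rows for one aligned allele set.

    d_nt uses K2P with gamma alpha = 1; d_aa uses amino-acid p-distance.
    """
    nt = [r.sequence for r in records]
    aa = translate_alignment(nt)
    aa_unique = sorted(set(aa))
    d_nt, d_nt_se = mean_divergence(nt, "k2p", 1.0, bootstrap_reps, seed)
    d_aa, d_aa_se = mean_divergence(aa_unique, "p", None, bootstrap_reps, seed)
    div = DiversityResult(
        s_nt=segregating_sites(nt),
        s_aa=segregating_sites(aa_unique),
        pi=nucleotide_diversity(nt),
        d_nt=d_nt,
        d_nt_se=d_nt_se,
        d_aa=d_aa,
        d_aa_se=d_aa_se,
        n_nt=len(nt),
        n_aa=len(aa_unique),
    )
    caln = build_codon_alignment(records)
    pbr, nonpbr = partition_codons(caln, mask)
    r_pbr = nei_gojobori_dnds(pbr, "PBR", bootstrap_reps, seed)
    r_non = nei_gojobori_dnds(nonpbr, "non-PBR", bootstrap_reps, seed)
    return div, r_pbr, r_non
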