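"""The four-step amplicon filtering cascade.

1. depth gate: drop amplicons below a minimum read depth (default 4000);
2. artefact clustering: merge variants lying 1-2 substitutions from a
   deeper dominant when their depth is at most 25% of the dominant's
   (deeper 1-2 bp variants become "subdominant" clusters of their own);
3. frequency threshold: keep clusters above a per-amplicon frequency,
   calibrated automatically as the best match between technical duplicate
   pairs when no threshold is given;
4. chimera screen: flag clusters whose dominant is a prefix/suffix splice
   of two deeper equal-length clusters.

Frequencies are cluster depth over total post-demultiplex amplicon depth,
computed after merging.  Different-length variants never merge: the 3-bp
deletion separates true allele length classes, not PCR artefacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import Amplicon, AmpliconSet

log = logging.getLogger(__name__)


@dataclass
class CallingConfig:
    min_amplicon_depth: int = 4000
    max_merge_mismatches: int = 2
    merge_depth_ratio: float = 0.25
    frequency_threshold: float | str = "auto"
    threshold_grid: tuple[float, float, float] = (0.005, 0.10, 0.001)

    def __post_init__(self) -> None:
        if not 0.0 < self.merge_depth_ratio < 1.0:
            raise ValueError("merge_depth_ratio must lie in (0, 1)")
        lo, hi, step = self.threshold_grid
        if not (lo <= hi and step > 0):
            raise ValueError("threshold_grid must be a non-empty ascending range")

    def grid(self) -> np.ndarray:
        lo, hi, step = self.threshold_grid
        return np.arange(lo, hi + step / 2.0, step)


@dataclass
class Cluster:
    """A dominant read variant plus the artefact variants merged into it."""

    dominant_sequence: str
    dominant_depth: int
    merged: list[tuple[str, int, int]] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)
    frequency: float = 0.0
    chimera_parents: tuple[str, str, int] | None = None

    @property
    def cluster_depth(self) -> int:
        return self.dominant_depth + sum(d for _, d, _ in self.merged)


@dataclass
class ClusteredAmplicon:
    amplicon: Amplicon
    clusters: list[Cluster]

    def called_sequences(self, threshold: float) -> frozenset[str]:
        """Allele sequences at this threshold: unflagged-chimera clusters
        with frequency >= threshold."""
        return frozenset(
            c.dominant_sequence
            for c in self.clusters
            if "chimera" not in c.flags and c.frequency >= threshold
        )


def hamming(a: str, b: str) -> int | None:
    """Substitution distance between equal-length strings; None otherwise."""
    if len(a) != len(b):
        return None
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# step 1: depth gate
# ---------------------------------------------------------------------------

def filter_amplicon_depth(
    amplicons: AmpliconSet, cfg: CallingConfig
) -> tuple[AmpliconSet, list[tuple[str, int]]]:
    """Keep amplicons with total depth >= the minimum; report the dropped."""
    kept, dropped = [], []
    for a in amplicons:
        if a.total_depth >= cfg.min_amplicon_depth:
            kept.append(a)
        else:
            dropped.append((a.amplicon_id, a.total_depth))
            log.info("amplicon %s dropped: depth %d < %d",
                     a.amplicon_id, a.total_depth, cfg.min_amplicon_depth)
    return AmpliconSet(kept), dropped


# ---------------------------------------------------------------------------
# step 2: artefact clustering
# ---------------------------------------------------------------------------

def cluster_variants(amplicon: Amplicon, cfg: CallingConfig) -> list[Cluster]:
    """Greedy depth-ordered clustering of an amplicon's read variants.

    A variant within ``max_merge_mismatches`` substitutions of an existing
    cluster's dominant is merged when its depth is at most
    ``merge_depth_ratio`` of that dominant's depth (assignment goes to the
    deepest eligible dominant); a near variant too deep to be an artefact
    opens a new cluster flagged ``subdominant``; anything else opens a new
    unflagged cluster.  Read depth is conserved.
    """
    total = amplicon.total_depth
    variants = sorted(amplicon.variants, key=lambda v: (-v.depth, v.sequence))
    clusters: list[Cluster] = []
    for v in variants:
        near = []
        for c in clusters:
            d = hamming(v.sequence, c.dominant_sequence)
            if d is not None and 1 <= d <= cfg.max_merge_mismatches:
                near.append((c, d))
        mergeable = [
            (c, d) for c, d in near
            if v.depth <= cfg.merge_depth_ratio * c.dominant_depth
        ]
        if mergeable:
            # clusters were created in depth order, so the first eligible
            # dominant is the deepest (ties already lexicographic)
            c, d = mergeable[0]
            c.merged.append((v.sequence, v.depth, d))
        elif near:
            clusters.append(Cluster(v.sequence, v.depth, flags={"subdominant"}))
        else:
            clusters.append(Cluster(v.sequence, v.depth))
    for c in clusters:
        c.frequency = c.cluster_depth / total if total else 0.0
    return clusters


# ---------------------------------------------------------------------------
# step 4 machinery: chimera screen (run before threshold filtering)
# ---------------------------------------------------------------------------

def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def detect_chimeras(clusters: list[Cluster]) -> list[Cluster]:
    """Flag clusters whose dominant is a breakpoint splice of two deeper,
    distinct, equal-length cluster dominants; returns the flagged clusters."""
    flagged = []
    for c in clusters:
        L = len(c.dominant_sequence)
        parents = [
            p for p in clusters
            if p is not c
            and len(p.dominant_sequence) == L
            and p.cluster_depth > c.cluster_depth
            and p.dominant_sequence != c.dominant_sequence
        ]
        found = None
        for pa in parents:
            lcp = _common_prefix(c.dominant_sequence, pa.dominant_sequence)
            if lcp == 0:
                continue
            for pb in parents:
                if pb is pa or pb.dominant_sequence == pa.dominant_sequence:
                    continue
                lsuf = _common_prefix(
                    c.dominant_sequence[::-1], pb.dominant_sequence[::-1]
                )
                k_lo = max(1, L - lsuf)
                k_hi = min(lcp, L - 1)
                if k_lo <= k_hi:
                    found = (pa.dominant_sequence, pb.dominant_sequence, k_lo)
                    break
            if found:
                break
        if found:
            c.flags.add("chimera")
            c.chimera_parents = found
            flagged.append(c)
            log.info("chimera flagged at frequency %.4f (breakpoint %d)",
                     c.frequency, found[2])
    return flagged


def cluster_amplicons(amplicons: AmpliconSet, cfg: CallingConfig
                      ) -> list[ClusteredAmplicon]:
    """Cluster every amplicon and run the chimera screen."""
    out = []
    for a in amplicons:
        clusters = cluster_variants(a, cfg)
        detect_chimeras(clusters)
        out.append(ClusteredAmplicon(a, clusters))
    return out


# ---------------------------------------------------------------------------
# step 3: duplicate-calibrated frequency threshold
# ---------------------------------------------------------------------------

class CalibrationError(RuntimeError):
    pass


def calibrate_threshold(
    clustered: list[ClusteredAmplicon], cfg: CallingConfig
) -> tuple[float, list[dict]]:
    """Choose the per-amplicon frequency threshold by best match between
    technical duplicate pairs.

    For each grid value the objective is lexicographic: number of pairs
    with identical provisional allele sets, then mean Jaccard similarity.
    The smallest grid value attaining the maximum is returned, with the
    full objective curve as diagnostics.
    """
    by_id = {ca.amplicon.amplicon_id: ca for ca in clustered}
    groups: dict[str, list[ClusteredAmplicon]] = {}
    for ca in clustered:
        g = ca.amplicon.duplicate_group
        if g:
            groups.setdefault(g, []).append(ca)
    pairs = [sorted(v, key=lambda ca: ca.amplicon.amplicon_id)
             for v in groups.values() if len(v) == 2]
    if not pairs:
        raise CalibrationError(
            "no technical duplicate pairs available; set an explicit "
            "frequency_threshold instead of 'auto'"
        )
    curve = []
    best = None
    best_t = None
    for t in cfg.grid():
        exact = 0
        jaccards = []
        for a, b in pairs:
            sa, sb = a.called_sequences(t), b.called_sequences(t)
            if sa == sb:
                exact += 1
            union = sa | sb
            jaccards.append(len(sa & sb) / len(union) if union else 1.0)
        mean_j = float(np.mean(jaccards))
        curve.append({"threshold": float(t), "exact_pairs": exact,
                      "mean_jaccard": mean_j, "n_pairs": len(pairs)})
        score = (exact, mean_j)
        if best is None or score > best:
            best = score
            best_t = float(t)
    assert best_t is not None
    return best_t, curve


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------

@dataclass
class GenotypeCall:
    individual_id: str
    alleles: frozenset[str]  # allele sequences
    source_amplicons: tuple[str, ...]
    duplicate_status: str  # "single" | "match" | "mismatch"


@dataclass
class CallingResult:
    genotypes: dict[str, GenotypeCall]
    threshold: float
    clustered: list[ClusteredAmplicon]
    dropped_amplicons: list[tuple[str, int]]
    calibration_curve: list[dict]
    allele_depths: dict[str, int]  # sequence -> summed cluster depth

    @property
    def duplicate_concordance(self) -> float:
        """Fraction of evaluable duplicate pairs whose genotypes match."""
        evaluated = [g for g in self.genotypes.values()
                     if g.duplicate_status in ("match", "mismatch")]
        if not evaluated:
            return float("nan")
        return sum(g.duplicate_status == "match" for g in evaluated) / len(evaluated)


def call_genotypes(
    clustered: list[ClusteredAmplicon], threshold: float
) -> dict[str, GenotypeCall]:
    """Per-individual allele sets at a threshold, reconciling duplicates.

    Duplicate amplicons of an individual are compared; on disagreement the
    genotype comes from the higher-depth amplicon and the individual is
    flagged ``mismatch``.
    """
    by_ind: dict[str, list[ClusteredAmplicon]] = {}
    for ca in clustered:
        by_ind.setdefault(ca.amplicon.individual_id, []).append(ca)
    calls: dict[str, GenotypeCall] = {}
    for ind, cas in sorted(by_ind.items()):
        cas = sorted(cas, key=lambda ca: ca.amplicon.amplicon_id)
        sets = [ca.called_sequences(threshold) for ca in cas]
        ids = tuple(ca.amplicon.amplicon_id for ca in cas)
        if len(cas) == 1:
            calls[ind] = GenotypeCall(ind, sets[0], ids, "single")
        else:
            if all(s == sets[0] for s in sets[1:]):
                calls[ind] = GenotypeCall(ind, sets[0], ids, "match")
            else:
                deepest = max(cas, key=lambda ca: ca.amplicon.total_depth)
                log.warning("individual %s: duplicate amplicons disagree; "
                            "using %s", ind, deepest.amplicon.amplicon_id)
                calls[ind] = GenotypeCall(
                    ind, deepest.called_sequences(threshold), ids, "mismatch"
                )
    return calls


def run_calling(amplicons: AmpliconSet, cfg: CallingConfig | None = None
                ) -> CallingResult:
    """Full cascade: depth gate, clustering, chimera screen, threshold
    (calibrated if 'auto'), genotype calling."""
    cfg = cfg or CallingConfig()
    kept, dropped = filter_amplicon_depth(amplicons, cfg)
    clustered = cluster_amplicons(kept, cfg)
    if cfg.frequency_threshold == "auto":
        threshold, curve = calibrate_threshold(clustered, cfg)
    else:
        threshold = float(cfg.frequency_threshold)  # type: ignore[arg-type]
        curve = []
    genotypes = call_genotypes(clustered, threshold)
    depths: dict[str, int] = {}
    for ca in clustered:
        for c in ca.clusters:
            if "chimera" not in c.flags and c.frequency >= threshold:
                depths[c.dominant_sequence] = (
                    depths.get(c.dominant_sequence, 0) + c.cluster_depth
                )
    return CallingResult(genotypes, threshold, clustered, dropped, curve, depths)
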