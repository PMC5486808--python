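"""Distance-based phylogeny substrate for the per-site selection test:
K2P distance matrices, neighbor-joining trees (scikit-bio agglomeration,
negative branch-length estimates clamped to zero), bipartition bootstrap
support, and Fitch/Hartigan parsimony ancestral codon states with a
nonsynonymous-minimizing tie-break.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .codon import codon_differences, _usable
from .diversity import pairwise_distance

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distance matrix and NJ
# ---------------------------------------------------------------------------

def build_distance_matrix(
    sequences: dict[str, str], model: str = "k2p", gamma_alpha: float | None = None
) -> DistanceMatrix:
    """All-pairs distances; pairs undefined under K2P fall back to
    p-distance (logged)."""
    ids = list(sequences)
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa")
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sequences[ids[i]], sequences[ids[j]]
            try:
                d = pairwise_distance(a, b, model, gamma_alpha)
            except ValueError:
                d = pairwise_distance(a, b, "p")
                log.info("pair (%s, %s): %s undefined, p-distance used",
                         ids[i], ids[j], model)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch-length estimates are clamped
    to zero and the clamped amount logged."""
    tree = _skbio_nj(matrix)
    clamped = 0.0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            clamped += -node.length
            node.length = 0.0
    if clamped:
        log.info("clamped %.6f of negative NJ branch length to zero", clamped)
    return tree


# ---------------------------------------------------------------------------
# bootstrap support
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, canonicalized as the side not containing
    the lexicographically smallest leaf."""
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves - side) < 2:
            continue
        parts.add(frozenset(leaves - side) if ref in side else side)
    return parts


def bootstrap_support(
    sequences: dict[str, str],
    reps: int = 1000,
    seed: int | None = None,
    model: str = "k2p",
    gamma_alpha: float | None = None,
) -> TreeNode:
    """NJ tree with internal-node bootstrap support (% of column-resampled
    replicates containing each internal bipartition)."""
    tree = nj_tree(build_distance_matrix(sequences, model, gamma_alpha))
    ids = list(sequences)
    L = len(next(iter(sequences.values())))
    rng = np.random.default_rng(seed)
    counts: Counter[frozenset[str]] = Counter()
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        resampled = {
            k: "".join(sequences[k][c] for c in cols) for k in ids
        }
        rep_tree = nj_tree(build_distance_matrix(resampled, model, gamma_alpha))
        counts.update(_bipartitions(rep_tree))
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves - side) < 2:
            continue
        key = frozenset(leaves - side) if ref in side else side
        node.name = str(int(round(100.0 * counts[key] / reps)))
    return tree


# ---------------------------------------------------------------------------
# ancestral codon states (Fitch/Hartigan parsimony)
# ---------------------------------------------------------------------------

def _label_internal(tree: TreeNode) -> None:
    i = 0
    for node in tree.non_tips(include_self=True):
        # bootstrap labels (if any) stay in .name; ancestral ids are separate
        node.anc_id = f"node{i}"
        i += 1
    for tip in tree.tips():
        tip.anc_id = tip.name


def _nonsyn_cost(c1: str, c2: str) -> float:
    return codon_differences(c1, c2)[1]


def fitch_site(tree: TreeNode, states: dict[str, str]) -> tuple[dict[str, str], int]:
    """Parsimony reconstruction of one codon site.

    ``states`` maps leaf name -> codon; leaves with gapped/unusable codons
    are uninformative.  Returns assigned states for every node (by
    ``anc_id``) and the parsimony change count.  Ties are resolved by
    minimizing implied nonsynonymous changes, then lexicographically.
    """
    observed = sorted({c for c in states.values() if _usable(c)})
    assignment: dict[str, str] = {}
    if not observed:
        for node in tree.traverse(include_self=True):
            assignment[node.anc_id] = "---"
        return assignment, 0
    universal = frozenset(observed)
    sets: dict[int, frozenset[str]] = {}
    score = 0
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            c = states.get(node.name, "---")
            sets[id(node)] = frozenset([c]) if _usable(c) else universal
        else:
            child_sets = [sets[id(ch)] for ch in node.children]
            cnt: Counter[str] = Counter()
            for s in child_sets:
                cnt.update(s)
            best = max(cnt.values())
            sets[id(node)] = frozenset(s for s, c in cnt.items() if c == best)
            score += len(child_sets) - best
    # top-down assignment
    for node in tree.preorder(include_self=True):
        options = sorted(sets[id(node)])
        if node.is_tip():
            c = states.get(node.name, "---")
            assignment[node.anc_id] = c if _usable(c) else assignment[node.parent.anc_id]
            continue
        if node.parent is None:
            chosen = min(options)
        else:
            parent_state = assignment[node.parent.anc_id]
            if parent_state in sets[id(node)]:
                chosen = parent_state
            else:
                chosen = min(options, key=lambda c: (_nonsyn_cost(parent_state, c), c))
        assignment[node.anc_id] = chosen
    return assignment, score


def ancestral_codons(
    tree: TreeNode, rows: dict[str, list[str]]
) -> tuple[dict[str, list[str]], list[int]]:
    """Per-site Fitch ancestral codons for every node.

    Returns (states-by-node over sites, per-site parsimony change counts).
    Leaf names of ``tree`` must match the keys of ``rows``.
    """
    _label_internal(tree)
    n_sites = len(next(iter(rows.values())))
    by_node: dict[str, list[str]] = {
        node.anc_id: [] for node in tree.traverse(include_self=True)
    }
    scores = []
    for site in range(n_sites):
        states = {name: codons[site] for name, codons in rows.items()}
        assignment, score = fitch_site(tree, states)
        for key, st in assignment.items():
            by_node[key].append(st)
        scores.append(score)
    return by_node, scores
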