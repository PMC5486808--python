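"""Phylogeny substrate and per-site selection: NJ exactness on additive
matrices, Fitch counts against brute-force minimal assignments, and the
binomial site test against closed-form tails."""

import itertools
import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from wadermhc.codon import codon_differences, _usable
from wadermhc.diversity import CodonAlignment, build_codon_alignment
from wadermhc.io import SequenceRecord
from wadermhc.phylo import (
    _bipartitions,
    ancestral_codons,
    bootstrap_support,
    build_distance_matrix,
    fitch_site,
    nj_tree,
)
from wadermhc.selection import expected_syn_fraction, run_selection, slac_test
from wadermhc.simulate import SimulationConfig, generate_allele_pool
from wadermhc.validate import align_exon3


class TestDistanceMatrix:
    def test_identical_triple_zero(self):
        dm = build_distance_matrix({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        assert np.allclose(dm.data, 0.0)

    def test_symmetry_and_pair_oracle(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), size=50))
        seqs = {}
        for k in "abcd":
            s = list(base)
            for i in range(50):
                if rng.random() < 0.1:
                    s[i] = str(rng.choice(list("ACGT")))
            seqs[k] = "".join(s)
        dm = build_distance_matrix(seqs, "k2p")
        from wadermhc.diversity import pairwise_distance

        ids = list(seqs)
        for i, j in itertools.combinations(range(4), 2):
            expected = pairwise_distance(seqs[ids[i]], seqs[ids[j]], "k2p")
            assert dm.data[i, j] == pytest.approx(expected)
            assert dm.data[j, i] == pytest.approx(expected)

    def test_needs_three_taxa(self):
        with pytest.raises(ValueError):
            build_distance_matrix({"a": "ACGT", "b": "ACGT"})


def random_additive_tree(rng, n):
    """Random binary tree with positive branch lengths; returns (TreeNode,
    exact leaf distance matrix)."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 1.0)))
             for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        parent.append(nodes[j])
        parent.append(nodes[i])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for x in nodes:
        root.append(x)
    names = [t.name for t in root.tips()]
    mat = np.zeros((n, n))
    for a, b in itertools.combinations(names, 2):
        d = root.find(a).distance(root.find(b))
        ia, ib = names.index(a), names.index(b)
        mat[ia, ib] = mat[ib, ia] = d
    return root, DistanceMatrix(mat, names)


class TestNeighborJoining:
    def test_three_taxon_hand_solution(self):
        """d(AB)=2, d(AC)=3, d(BC)=4 -> branches A:0.5, B:1.5, C:2.5
        (solving the three-point equations by hand)."""
        dm = DistanceMatrix([[0, 2, 3], [2, 0, 4], [3, 4, 0]], ["A", "B", "C"])
        tree = nj_tree(dm)
        tips = {t.name: t.length for t in tree.tips()}
        assert tips == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    @pytest.mark.parametrize("seed", range(8))
    def test_additive_matrix_exact_recovery(self, seed):
        """On an additive matrix NJ reproduces topology and all pairwise
        path lengths."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        true_tree, dm = random_additive_tree(rng, n)
        tree = nj_tree(dm)
        assert _bipartitions(tree) == _bipartitions(true_tree)
        for a, b in itertools.combinations(dm.ids, 2):
            d = tree.find(a).distance(tree.find(b))
            assert d == pytest.approx(dm[a, b], abs=1e-9)

    def test_ultrametric_equal_distances_path_lengths(self):
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), list("abcd"))
        tree = nj_tree(dm)
        for a, b in itertools.combinations("abcd", 2):
            assert tree.find(a).distance(tree.find(b)) == pytest.approx(1.0)


class TestBootstrap:
    def _two_clade_seqs(self):
        a = "A" * 30
        b = "T" * 15 + "A" * 15
        return {"a1": a, "a2": a, "a3": a[:29] + "G",
                "b1": b, "b2": b, "b3": b[:1] + "C" + b[2:]}

    def test_diagnostic_split_high_support(self):
        tree = bootstrap_support(self._two_clade_seqs(), reps=100, seed=0, model="p")
        supports = [int(n.name) for n in tree.non_tips(include_self=False)
                    if n.name and n.name.isdigit()]
        assert max(supports) >= 95

    def test_single_rep_support_binary(self):
        tree = bootstrap_support(self._two_clade_seqs(), reps=1, seed=0, model="p")
        supports = [int(n.name) for n in tree.non_tips(include_self=False)
                    if n.name and n.name.isdigit()]
        assert set(supports) <= {0, 100}

    def test_seeded_determinism(self):
        t1 = bootstrap_support(self._two_clade_seqs(), reps=50, seed=3, model="p")
        t2 = bootstrap_support(self._two_clade_seqs(), reps=50, seed=3, model="p")
        assert str(t1) == str(t2)


def brute_force_parsimony(tree, states):
    """Minimal total changes over all internal-state assignments."""
    observed = sorted({c for c in states.values() if _usable(c)})
    internals = list(tree.non_tips(include_self=True))
    best = math.inf
    for combo in itertools.product(observed, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        for tip in tree.tips():
            c = states.get(tip.name)
            assign[id(tip)] = c if _usable(c) else None
        total = 0
        for node in tree.traverse(include_self=False):
            a, b = assign[id(node.parent)], assign[id(node)]
            if a is not None and b is not None and a != b:
                total += 1
        best = min(best, total)
    return best


class TestAncestralCodons:
    def _tree_and_rows(self, rows):
        seqs = {k: "".join(v) for k, v in rows.items()}
        tree = nj_tree(build_distance_matrix(seqs, "p"))
        return tree, rows

    def test_invariant_site_uniform_ancestors(self):
        rows = {k: ["AAA"] for k in "abcd"}
        tree, rows = self._tree_and_rows(
            {k: ["AAA", c] for k, c in zip("abcd", ["TTT", "TTC", "GGG", "GGA"])}
        )
        states, scores = ancestral_codons(tree, rows)
        assert scores[0] == 0
        assert {v[0] for v in states.values()} == {"AAA"}

    def test_tie_break_minimizes_nonsynonymous(self):
        """On a two-leaf star the ancestor must equal one of the leaves;
        with a third distant leaf the tie resolves toward fewer
        nonsynonymous implied changes, then lexicographically."""
        root = TreeNode.read(["(a:1,b:1,c:1);"])
        rows = {"a": ["TTT"], "b": ["TTC"], "c": ["TTT"]}
        states, score = {}, None
        states_by_node, scores = ancestral_codons(root, rows)
        assert scores[0] == 1
        anc = states_by_node["node0"][0]
        assert anc == "TTT"  # majority state

    @pytest.mark.parametrize("seed", range(6))
    def test_fitch_count_equals_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        codons = ["TTT", "TTC", "AAA", "AGA", "GGG", "CTG"]
        n = int(rng.integers(4, 7))
        rows = {f"t{i}": [str(rng.choice(codons)) for _ in range(3)]
                for i in range(n)}
        seqs = {k: "".join(v) for k, v in rows.items()}
        tree = nj_tree(build_distance_matrix(seqs, "p"))
        _, scores = ancestral_codons(tree, rows)
        for site in range(3):
            states = {k: rows[k][site] for k in rows}
            assert scores[site] == brute_force_parsimony(tree, states)


class TestSlac:
    def test_no_changes_site_neutral(self):
        aln = CodonAlignment({k: ["AAA"] for k in "abc"}, [93])
        seqs = {k: "AAA" for k in "abc"}
        tree = nj_tree(DistanceMatrix(np.zeros((3, 3)), list("abc")))
        res = slac_test(tree, aln)
        assert res[0].classification == "neutral"
        assert res[0].p_value == 1.0

    def test_binomial_tail_closed_form(self):
        """A site with k nonsynonymous and 0 synonymous changes has the
        p-value of the closed-form two-tailed binomial at the neutral
        synonymous fraction."""
        # star tree with 7 leaves: 6 carry nonsynonymous variants of AAA
        leaves = list("abcdefg")
        tree = TreeNode.read(["(" + ",".join(f"{x}:1" for x in leaves) + ");"])
        variant_codons = ["ACA", "AGA", "ATA", "CAA", "GAA", "AAC"]
        rows = {"a": ["AAA"]}
        for leaf, c in zip(leaves[1:], variant_codons):
            rows[leaf] = [c]
        aln = CodonAlignment(rows, [93])
        res = slac_test(tree, aln)[0]
        assert res.obs_syn == 0.0
        assert res.obs_nonsyn == 6.0
        f = res.expected_syn_fraction
        # closed-form two-tailed binomial tail for 0 successes in 6 trials
        pmf = [math.comb(6, k) * f**k * (1 - f) ** (6 - k) for k in range(7)]
        p0 = pmf[0]
        expected_p = sum(p for p in pmf if p <= p0 + 1e-12)
        assert res.p_value == pytest.approx(expected_p, rel=1e-9)

    def test_classification_monotone_in_threshold(self):
        pool, mask = generate_allele_pool(SimulationConfig(seed=21))
        aln = build_codon_alignment(align_exon3(pool))
        tree, res_10 = run_selection(aln, p_threshold=0.1)
        res_05 = slac_test(tree, aln, p_threshold=0.05)
        pos05 = {r.position for r in res_05 if r.classification == "positive"}
        pos10 = {r.position for r in res_10 if r.classification == "positive"}
        assert pos05 <= pos10

    def test_positive_calls_enriched_in_pbr(self):
        """A pool generated with nonsynonymous excess at PBR codons yields
        positive calls concentrated in the PBR."""
        pool, mask = generate_allele_pool(SimulationConfig(seed=22))
        aln = build_codon_alignment(align_exon3(pool))
        _, res = run_selection(aln)
        positives = [r.position for r in res if r.classification == "positive"]
        assert positives, "expected at least one positive site"
        frac_pbr = np.mean([p in mask for p in positives])
        assert frac_pbr > len(mask) / aln.n_codons  # enriched vs chance
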