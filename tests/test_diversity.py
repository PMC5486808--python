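"""Diversity statistics against independent oracles: brute-force column
scans, closed-form K2P, hand-enumerated Nei-Gojobori pathway counts, and
Biopython's separate NG86 implementation."""

import math
import warnings

import numpy as np
import pytest

from wadermhc.codon import (
    codon_differences,
    codon_sites,
    jukes_cantor,
    pair_counts,
    pair_dn_ds,
)
from wadermhc.diversity import (
    CodonAlignment,
    build_codon_alignment,
    kimura_2p,
    mean_divergence,
    nei_gojobori_dnds,
    nucleotide_diversity,
    pairwise_distance,
    partition_codons,
    segregating_sites,
)
from wadermhc.io import SequenceRecord


def random_seqs(rng, n, L, alphabet="ACGT"):
    return ["".join(rng.choice(list(alphabet), size=L)) for _ in range(n)]


class TestSegregatingSites:
    def test_identical(self):
        assert segregating_sites(["ACGT", "ACGT"]) == 0

    def test_three_differing_columns(self):
        assert segregating_sites(["AAAAAA", "ATTAAT"]) == 3

    def test_gap_columns_counted_by_nongap_states(self):
        # column 0: {A} plus gap -> not segregating; column 1: {C,G} -> segregating
        assert segregating_sites(["AC", "-G", "AC"]) == 1

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            seqs = random_seqs(rng, 5, 30, "ACGT-")
            expected = sum(
                len({c for c in col if c != "-"}) >= 2 for col in zip(*seqs)
            )
            assert segregating_sites(seqs) == expected

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            segregating_sites(["ACGT"])


class TestNucleotideDiversity:
    def test_identical(self):
        assert nucleotide_diversity(["ACGT"] * 3) == 0.0

    def test_single_difference_over_ten_sites(self):
        assert nucleotide_diversity(["AAAAAAAAAA", "AAAAAAAAAT"]) == pytest.approx(0.1)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(2)
        seqs = random_seqs(rng, 6, 40, "ACGT-")
        total, pairs = 0.0, 0
        for i in range(6):
            for j in range(i + 1, 6):
                ov = mm = 0
                for x, y in zip(seqs[i], seqs[j]):
                    if "-" in (x, y):
                        continue
                    ov += 1
                    mm += x != y
                if ov:
                    total += mm / ov
                    pairs += 1
        assert nucleotide_diversity(seqs) == pytest.approx(total / pairs)


class TestPairwiseDistance:
    def test_identical_zero_both_models(self):
        assert pairwise_distance("ACGT", "ACGT", "p") == 0.0
        assert pairwise_distance("ACGT", "ACGT", "k2p") == 0.0

    def test_k2p_closed_form(self):
        """K2P from observed P, Q equals Kimura's closed form."""
        P, Q = 0.1, 0.05
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert kimura_2p(P, Q) == pytest.approx(expected)
        # a sequence pair realizing exactly P=0.1, Q=0.05 over 20 sites:
        # 2 transitions (A<->G), 1 transversion (A<->C)
        a = "A" * 20
        b = "G" * 2 + "C" * 1 + "A" * 17
        assert pairwise_distance(a, b, "k2p") == pytest.approx(expected)

    def test_k2p_domain_violation(self):
        with pytest.raises(ValueError):
            pairwise_distance("A" * 10, "G" * 10, "k2p")

    def test_distance_ordering_p_k2p_gamma(self):
        """p <= K2P <= K2P(gamma=1) wherever defined."""
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(50):
            a = random_seqs(rng, 1, 60)[0]
            b = list(a)
            for i in range(len(b)):
                if rng.random() < 0.2:
                    b[i] = str(rng.choice(list("ACGT")))
            b = "".join(b)
            try:
                k2p = pairwise_distance(a, b, "k2p")
                k2pg = pairwise_distance(a, b, "k2p", 1.0)
            except ValueError:
                continue
            p = pairwise_distance(a, b, "p")
            assert p <= k2p + 1e-12 <= k2pg + 1e-12
            checked += 1
        assert checked > 10


class TestMeanDivergence:
    def test_identical_zero_zero(self):
        d, se = mean_divergence(["ACGT", "ACGT"], "p", bootstrap_reps=50, seed=0)
        assert d == 0.0 and se == 0.0

    def test_se_stable_across_seeds(self):
        rng = np.random.default_rng(4)
        seqs = random_seqs(rng, 5, 100)
        ses = [
            mean_divergence(seqs, "p", bootstrap_reps=400, seed=s)[1]
            for s in (1, 2)
        ]
        assert ses[0] == pytest.approx(ses[1], rel=0.25)

    def test_se_shrinks_with_replicated_columns(self):
        """Bootstrap SE tends to zero as the site pattern is duplicated."""
        rng = np.random.default_rng(5)
        base = random_seqs(rng, 4, 20)
        se = []
        for k in (1, 16):
            seqs = [s * k for s in base]
            se.append(mean_divergence(seqs, "p", bootstrap_reps=300, seed=0)[1])
        assert se[1] < se[0] / 2


def _records(seqs):
    return [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]


class TestCodonAlignment:
    def test_partition_conservation(self):
        rng = np.random.default_rng(6)
        # 81 codons + 2-nt overhangs, frame positions 93..173
        seqs = random_seqs(rng, 3, 247)
        aln = build_codon_alignment(_records(seqs), deduplicate=False)
        assert aln.n_codons == 81
        pbr, non = partition_codons(aln)
        assert pbr.n_codons == 12
        assert pbr.n_codons + non.n_codons == aln.n_codons

    def test_empty_mask_all_nonpbr(self):
        rng = np.random.default_rng(7)
        aln = build_codon_alignment(_records(random_seqs(rng, 2, 247)),
                                    deduplicate=False)
        pbr, non = partition_codons(aln, frozenset())
        assert pbr.n_codons == 0 and non.n_codons == 81

    def test_mask_outside_frame_raises(self):
        rng = np.random.default_rng(8)
        aln = build_codon_alignment(_records(random_seqs(rng, 2, 247)),
                                    deduplicate=False)
        with pytest.raises(ValueError, match="200"):
            partition_codons(aln, frozenset({96, 200}))

    def test_flank_duplicates_collapse(self):
        core = "ATGAAACCC"
        a = "GT" + core + "CA"
        b = "AA" + core + "TT"  # differs only in the incomplete codons
        aln = build_codon_alignment(_records([a, b]))
        assert len(aln.rows) == 1
        assert aln.dropped_duplicates == {"s1": "s0"}


class TestNeiGojobori:
    def test_fourfold_site_counts(self):
        # glycine GGG: third position fully synonymous -> 1 syn site
        s, n = codon_sites("GGG")
        assert s == pytest.approx(1.0)
        assert s + n == pytest.approx(3.0)

    def test_hand_enumerated_toy_pair(self):
        """TTT<->TTC is one synonymous difference; AAA<->AGA one
        nonsynonymous; site counts match hand enumeration."""
        sd, nd = codon_differences("TTT", "TTC")
        assert (sd, nd) == (1.0, 0.0)
        sd, nd = codon_differences("AAA", "AGA")
        assert (sd, nd) == (0.0, 1.0)
        c = pair_counts(["TTT", "AAA"], ["TTC", "AGA"])
        assert c.syn_diffs == 1.0 and c.nonsyn_diffs == 1.0
        # TTT: F; neighbors at pos3: TTC(F) syn, TTA(L), TTG(L) nonsyn;
        # pos1/2 all nonsynonymous -> 1/3 syn site before normalization
        s_ttt, n_ttt = codon_sites("TTT")
        assert s_ttt == pytest.approx(1.0 / 3.0)
        # AAA: K; neighbors AAG(K) syn at pos3 -> 1/3 syn site
        s_aaa, _ = codon_sites("AAA")
        assert s_aaa == pytest.approx(1.0 / 3.0)
        # AGA: R; syn neighbors AGG (pos3) and CGA (pos1) -> 2/3 syn site
        s_aga, _ = codon_sites("AGA")
        assert s_aga == pytest.approx(2.0 / 3.0)
        s_ttc, _ = codon_sites("TTC")
        assert c.syn_sites == pytest.approx(
            (s_ttt + s_ttc) / 2 + (s_aaa + s_aga) / 2
        )

    def test_two_step_pathway_average(self):
        """AAA<->AGG: both orders of the two changes, averaged at 0.5."""
        sd, nd = codon_differences("AAA", "AGG")
        # path 1: AAA->AGA(R, nonsyn)->AGG(R, syn); path 2: AAA->AAG(K, syn)->AGG(R, nonsyn)
        assert sd == pytest.approx(1.0)
        assert nd == pytest.approx(1.0)

    def test_per_codon_site_sum_is_three(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            codon = "".join(rng.choice(list("ACGT"), size=3))
            if codon in ("TAA", "TAG", "TGA"):
                continue
            s, n = codon_sites(codon)
            assert s + n == pytest.approx(3.0)

    def test_matches_biopython_ng86(self):
        """Full pairwise dN/dS agrees with Biopython's independent NG86."""
        warnings.filterwarnings("ignore")
        from Bio.codonalign.codonseq import _ng86
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        rng = np.random.default_rng(10)
        table = unambiguous_dna_by_id[1]
        for _ in range(10):
            c1 = []
            while len(c1) < 30:
                c = "".join(rng.choice(list("ACGT"), size=3))
                if c not in ("TAA", "TAG", "TGA"):
                    c1.append(c)
            c2 = list(c1)
            for _ in range(4):
                i = int(rng.integers(30))
                p = int(rng.integers(3))
                while True:
                    b = str(rng.choice(list("ACGT")))
                    cand = c2[i][:p] + b + c2[i][p + 1:]
                    if cand not in ("TAA", "TAG", "TGA"):
                        break
                c2[i] = cand
            dn_bio, ds_bio = _ng86(c1, c2, 1.0, table)
            dn, ds = pair_dn_ds(c1, c2)
            assert dn == pytest.approx(dn_bio, abs=1e-9)
            assert ds == pytest.approx(abs(ds_bio), abs=1e-9)

    def test_synonymous_only_alignment_dn_zero(self):
        aln = CodonAlignment({"a": ["TTT", "GGG"], "b": ["TTC", "GGA"]}, [93, 94])
        # uncorrected proportions: 2 synonymous differences over 2 codons
        # exceed the Jukes-Cantor domain
        r = nei_gojobori_dnds(aln, bootstrap_reps=0, correct=False)
        assert r.dn == 0.0
        assert r.ds > 0.0

    def test_ds_zero_ratio_nan(self):
        aln = CodonAlignment({"a": ["AAA"], "b": ["AGA"]}, [93])
        r = nei_gojobori_dnds(aln, bootstrap_reps=0)
        assert r.ds == 0.0
        assert math.isnan(r.ratio)

    def test_reordering_invariance(self):
        rng = np.random.default_rng(11)
        seqs = random_seqs(rng, 4, 247)
        aln1 = build_codon_alignment(_records(seqs), deduplicate=False)
        aln2 = build_codon_alignment(_records(seqs[::-1]), deduplicate=False)
        r1 = nei_gojobori_dnds(aln1, bootstrap_reps=0)
        r2 = nei_gojobori_dnds(aln2, bootstrap_reps=0)
        assert r1.dn == pytest.approx(r2.dn)
        assert r1.ds == pytest.approx(r2.ds)

    def test_jukes_cantor_bounds(self):
        assert jukes_cantor(0.0) == 0.0
        with pytest.raises(ValueError):
            jukes_cantor(0.75)
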