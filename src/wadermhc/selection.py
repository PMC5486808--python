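"""Per-site selection inference in the SLAC (counting) family.

Pipeline: K2P distances -> neighbor-joining tree -> parsimony ancestral
codons -> per-site synonymous/nonsynonymous change counts along branches
(pathway-averaged for multi-step codon changes) -> per-site binomial test
of the observed synonymous fraction against the neutral expectation from
Nei-Gojobori potential-site counts -> classification at a p-value
threshold (default P = 0.1).

This is a single counting method on an NJ tree; ensembles of counting and
likelihood methods on recombination-aware trees can call different site
lists on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binomtest
from skbio import TreeNode

from .codon import codon_differences, codon_sites, _usable
from .diversity import CodonAlignment
from .frame import PBR_EXON3_DNDS
from .phylo import ancestral_codons, build_distance_matrix, nj_tree


@dataclass(frozen=True)
class SiteSelectionResult:
    position: int  # alignment amino-acid position
    obs_syn: float
    obs_nonsyn: float
    expected_syn_fraction: float
    dn_minus_ds: float
    p_value: float
    classification: str  # "positive" | "negative" | "neutral"
    in_pbr: bool


def site_counts(tree: TreeNode, rows: dict[str, list[str]]
                ) -> list[tuple[float, float]]:
    """Observed (synonymous, nonsynonymous) changes per site, summed over
    all branches between reconstructed ancestral states."""
    states, _ = ancestral_codons(tree, rows)
    n_sites = len(next(iter(rows.values())))
    edges = [
        (node.parent.anc_id, node.anc_id)
        for node in tree.traverse(include_self=False)
        if node.parent is not None
    ]
    out = []
    for site in range(n_sites):
        syn = nonsyn = 0.0
        for pa, ch in edges:
            c1, c2 = states[pa][site], states[ch][site]
            if not (_usable(c1) and _usable(c2)):
                continue
            s, n = codon_differences(c1, c2)
            syn += s
            nonsyn += n
        out.append((syn, nonsyn))
    return out


def expected_syn_fraction(codons: list[str]) -> float:
    """Neutral expectation of the synonymous fraction of changes at a site:
    mean synonymous share of Nei-Gojobori potential sites over the observed
    codons."""
    usable = [c for c in codons if _usable(c)]
    if not usable:
        return 0.0
    fracs = [codon_sites(c)[0] / 3.0 for c in usable]
    return sum(fracs) / len(fracs)


def slac_test(
    tree: TreeNode,
    aln: CodonAlignment,
    p_threshold: float = 0.1,
    pbr_mask: frozenset[int] = PBR_EXON3_DNDS,
) -> list[SiteSelectionResult]:
    """Classify each codon site as positive / negative / neutral at
    ``p_threshold``.

    Per site, the observed synonymous count is tested against the neutral
    synonymous fraction with a two-tailed binomial test; the sign of the
    normalized dN - dS decides the direction.  Sites with no inferred
    changes are neutral with p = 1.
    """
    counts = site_counts(tree, aln.rows)
    results = []
    for site, (syn, nonsyn) in enumerate(counts):
        position = aln.positions[site]
        col = [aln.rows[k][site] for k in aln.rows]
        f = expected_syn_fraction(col)
        es, en = 3.0 * f, 3.0 * (1.0 - f)
        ds = syn / es if es > 0 else 0.0
        dn = nonsyn / en if en > 0 else 0.0
        diff = dn - ds
        total = int(round(syn + nonsyn))
        if total <= 0:
            p = 1.0
        else:
            p = float(binomtest(int(round(syn)), total, f,
                                alternative="two-sided").pvalue)
        if p <= p_threshold and diff > 0:
            cls = "positive"
        elif p <= p_threshold and diff < 0:
            cls = "negative"
        else:
            cls = "neutral"
        results.append(SiteSelectionResult(
            position, syn, nonsyn, f, diff, p, cls, position in pbr_mask
        ))
    return results


def run_selection(
    aln: CodonAlignment,
    p_threshold: float = 0.1,
    pbr_mask: frozenset[int] = PBR_EXON3_DNDS,
) -> tuple[TreeNode, list[SiteSelectionResult]]:
    """Build the NJ tree from the codon alignment and run the site test."""
    sequences = {k: "".join(v) for k, v in aln.rows.items()}
    tree = nj_tree(build_distance_matrix(sequences, "k2p"))
    return tree, slac_test(tree, aln, p_threshold, pbr_mask)
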