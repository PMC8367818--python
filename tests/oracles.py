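"""Independent brute-force oracles used to cross-check the implementations.

Each oracle re-derives its quantity from first principles (exhaustive
enumeration, direct definitions), sharing no code path with the package
functions it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Data import CodonTable
from skbio import TreeNode

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
_BASES = "ACGT"


def ng86_oracle(codons_a, codons_b):
    """(S, N, Sd, Nd) by direct per-codon enumeration of sites and pathways."""

    def sites(codon):
        total = 0.0
        for pos in range(3):
            syn = valid = 0
            for b in _BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt in _STOPS:
                    continue
                valid += 1
                syn += _AA[alt] == _AA[codon]
            if valid:
                total += syn / valid
        return total

    def pathways(c1, c2):
        diffs = [i for i in range(3) if c1[i] != c2[i]]
        if not diffs:
            return 0.0, 0.0
        results = []
        for order in itertools.permutations(diffs):
            cur, syn, ok = c1, 0, True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt in _STOPS:
                    ok = False
                    break
                syn += _AA[cur] == _AA[nxt]
                cur = nxt
            if ok:
                results.append(syn)
        if not results:
            raise ValueError("all pathways blocked by stops")
        sd = sum(results) / len(results)
        return sd, len(diffs) - sd

    S = (sum(map(sites, codons_a)) + sum(map(sites, codons_b))) / 2.0
    N = 3.0 * len(codons_a) - S
    Sd = Nd = 0.0
    for c1, c2 in zip(codons_a, codons_b):
        sd, nd = pathways(c1, c2)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def rbh_oracle(hits_df, evalue_max=1e-5, c_min=0.3, aln_min=100):
    """Set of kept unordered RBH pairs by exhaustive double loop.

    A pair (a, b) is kept when each gene's single best non-self hit (max
    bitscore, ties by min evalue then lexicographic subject) is the other
    and at least one connecting direction passes all three filters.
    """
    rows = list(hits_df.itertuples(index=False))
    queries = sorted({r.query for r in rows})

    def best(q):
        cand = [r for r in rows if r.query == q and r.subject != q]
        if not cand:
            return None, None
        chosen = min(cand, key=lambda r: (-r.bitscore, r.evalue, r.subject))
        best_score = max(r.bitscore for r in cand)
        return chosen, best_score

    kept = set()
    for a in queries:
        row_a, best_a = best(a)
        if row_a is None:
            continue
        b = row_a.subject
        row_b, best_b = best(b)
        if row_b is None or row_b.subject != a:
            continue

        def passes(row, denom):
            c = row.bitscore / denom if denom > 0 else 0.0
            return (
                row.evalue <= evalue_max and c >= c_min and row.aln_length >= aln_min
            )

        if passes(row_a, best_a) or passes(row_b, best_b):
            kept.add(tuple(sorted((a, b))))
    return kept


def detect_groups_oracle(loci, family_filter, max_gap, min_size):
    """All maximal windows satisfying both criteria, by window enumeration."""
    fam = set(family_filter)
    out = []
    chroms = sorted({g.chrom for g in loci if g.family in fam})
    for chrom in chroms:
        genes = sorted(
            (g for g in loci if g.chrom == chrom and g.family in fam),
            key=lambda g: (g.start, g.end, g.gene_id),
        )
        n = len(genes)

        def gap_ok(i, j):
            return all(
                max(0, genes[k + 1].start - genes[k].end) <= max_gap
                for k in range(i, j)
            )

        for i in range(n):
            for j in range(i, n):
                if j - i + 1 < min_size or not gap_ok(i, j):
                    continue
                left_ext = i > 0 and max(0, genes[i].start - genes[i - 1].end) <= max_gap
                right_ext = (
                    j < n - 1 and max(0, genes[j + 1].start - genes[j].end) <= max_gap
                )
                if not left_ext and not right_ext:
                    out.append(tuple(g.gene_id for g in genes[i : j + 1]))
    return set(out)


def bh_oracle(pvalues):
    """Benjamini-Hochberg step-up from the definition."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted


def random_additive_tree(rng, n_taxa, min_bl=0.1, max_bl=1.0):
    """Random binary tree and its exact tip-to-tip distance matrix."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(name=t) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(min_bl, max_bl))
        b.length = float(rng.uniform(min_bl, max_bl))
        parent = TreeNode(children=[b, a])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    tree = nodes[0]
    dm = tree.tip_tip_distances()
    return tree, dm


def permutation_pearson_pvalue(x, y, n_perm, rng):
    """Two-sided permutation p-value for the Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    hits = 0
    for _ in range(n_perm):
        r = abs(np.corrcoef(x, rng.permutation(y))[0, 1])
        hits += r >= r_obs
    return (hits + 1) / (n_perm + 1)
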