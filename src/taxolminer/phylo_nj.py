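"""p-distance matrices and neighbour-joining trees with Newick round-trip.

The distance-based reconstruction used for the CYP725 and BAHD family
trees: proportion-of-differing-sites distances (pairwise deletion of
gap/ambiguous columns) and Saitou-Nei neighbour joining with deterministic
lexicographic tie-breaking.  Trees are scikit-bio ``TreeNode`` objects, so
Newick serialisation and tip-to-tip path lengths come for free.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "p_distance",
    "neighbor_joining",
    "write_newick",
    "read_newick",
]

_NUC_VALID = frozenset("ACGT")
_AA_VALID = frozenset("ACDEFGHIKLMNPQRSTVWY")


def p_distance(sequences: dict[str, str], alphabet: str = "auto") -> DistanceMatrix:
    """Pairwise p-distance matrix: mismatches / compared sites.

    Gap and ambiguous characters are excluded pairwise; a pair with zero
    comparable sites is an error.  Works identically for nucleotide and
    protein alignments (``alphabet`` picks the valid character set,
    "auto" infers it from the residues present).
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    names = list(sequences)
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    seqs = {k: v.upper() for k, v in sequences.items()}
    if alphabet == "auto":
        residues = set("".join(seqs.values())) - set("-.*X?")
        valid = _NUC_VALID if residues <= set("ACGTUN") else _AA_VALID
    elif alphabet == "nt":
        valid = _NUC_VALID
    elif alphabet == "aa":
        valid = _AA_VALID
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[names[i]], seqs[names[j]]
            comparable = mismatch = 0
            for x, y in zip(a, b):
                if x not in valid or y not in valid:
                    continue
                comparable += 1
                if x != y:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {names[i]} and {names[j]}"
                )
            d[i, j] = d[j, i] = mismatch / comparable
    return DistanceMatrix(d, ids=names)


def _tip_label(node_label) -> str:
    """Sort key for deterministic tie-breaking: the lexicographically
    smallest leaf name under a (possibly internal) working node."""
    return node_label


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    Q-matrix agglomeration with the standard branch-length formulas; among
    equal-Q pairs the lexicographically smallest pair of working-node labels
    (internal nodes inherit their smallest leaf label) is merged.  Negative
    branch-length estimates are clamped to zero when ``clamp_negative``; the
    number of clamped branches is recorded on the returned tree as
    ``tree.n_clamped``.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    # working state: labels (for tie-breaks), nodes, distance matrix
    labels = list(ids)
    nodes = [TreeNode(name=name) for name in ids]
    d = np.array(dm.data, dtype=float)
    n_clamped = 0

    def clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0 and clamp_negative:
            n_clamped += 1
            return 0.0
        return x

    while len(nodes) > 2:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = clamp(d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2)))
        lj = clamp(d[i, j] - (d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))))
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new_node = TreeNode(children=[child_i, child_j])
        new_label = min(labels[i], labels[j])
        # distances from the new node to the remaining nodes
        keep = [k for k in range(n) if k not in (i, j)]
        new_row = np.array(
            [(d[i, k] + d[j, k] - d[i, j]) / 2.0 for k in keep]
        )
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        nodes = [nodes[k] for k in keep] + [new_node]
        labels = [labels[k] for k in keep] + [new_label]

    # join the last two working nodes by the remaining distance
    a, b = nodes
    if a.is_tip() and not b.is_tip():
        a, b = b, a  # graft the tip onto the internal node's root
    a.length = None
    b.length = clamp(d[0, 1])
    a.append(b)
    tree = a
    tree.n_clamped = n_clamped
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"{path}: empty or missing Newick file")
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise ValueError(f"{path}: malformed Newick: {exc}") from exc
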