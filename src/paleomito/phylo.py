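"""Distance-based phylogenetic placement with bootstrap and outgroup rooting.

The third line of evidence for species identification: where does a
sample's consensus sequence fall among the candidate references? Trees
are built by neighbor joining on p-distances or the JC69/K80
corrections, supports come from column-resampling bootstrap, the tree
is rooted on a designated outgroup, and a query is assigned to the
panel reference that is its closest leaf within its smallest
well-supported clade.

Neighbor joining is implemented here with explicit deterministic
tie-breaking (taxon order) and clamping of negative branch-length
estimates to zero; on an additive distance matrix it returns the
generating tree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .msa import Msa
from .panel import ReferencePanel

__all__ = [
    "DistanceMatrix",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "root_with_outgroup",
    "clade_of",
    "bipartitions",
    "rf_distance",
    "write_newick",
]

MODELS = ("p", "JC69", "K80")
_TRANSITION_PAIRS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray = field(repr=False)
    model: str = "p"

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for i, t in enumerate(self.taxa):
                vals = " ".join(f"{x:.6f}" for x in self.matrix[i])
                fh.write(f"{t:<12}{vals}\n")


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(differing, transitions, transversions) between two code rows."""
    diff = a != b
    n_diff = int(np.count_nonzero(diff))
    ts = 0
    if n_diff:
        # in the A=0,C=1,G=2,T=3 code, transitions are exactly XOR == 2
        ts = int(np.count_nonzero((a[diff] ^ b[diff]) == 2))
    return n_diff, ts, n_diff - ts


def distance_matrix(msa: Msa, model: str = "K80") -> DistanceMatrix:
    """Pairwise distances from a gap/N-free alignment.

    p: proportion of differing columns. JC69: −(3/4)·ln(1 − 4p/3),
    finite only for p < 3/4. K80: −(1/2)·ln((1−2P−Q)·sqrt(1−2Q)) with
    transition proportion P and transversion proportion Q. Saturated
    pairs raise an error naming the pair.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if not msa.is_clean():
        raise ValueError("distances require a gap/N-free alignment")
    m = msa.matrix
    ncol = msa.n_columns
    if ncol == 0:
        raise ValueError("empty alignment")
    n = msa.n_seqs
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            n_diff, ts, tv = _pair_counts(m[i], m[j])
            p = n_diff / ncol
            if model == "p":
                d = p
            elif model == "JC69":
                if p >= 0.75:
                    raise ValueError(
                        f"JC69 saturated for pair ({msa.seq_ids[i]}, {msa.seq_ids[j]}): p={p:.3f}"
                    )
                d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            else:  # K80
                P, Q = ts / ncol, tv / ncol
                w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
                if w1 <= 0 or w2 <= 0:
                    raise ValueError(
                        f"K80 saturated for pair ({msa.seq_ids[i]}, {msa.seq_ids[j]})"
                    )
                d = -0.5 * np.log(w1 * np.sqrt(w2))
            out[i, j] = out[j, i] = d
    return DistanceMatrix(taxa=list(msa.seq_ids), matrix=out, model=model)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining with the Q-criterion.

    Ties in Q break to the smallest (i, j) index pair in the current
    taxon order, so the result is deterministic. Negative branch-length
    estimates are clamped to 0 and counted in
    ``tree.n_clamped_branches``.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.astype(float).copy()
    nodes = [TreeNode(name=t) for t in dm.taxa]
    clamped = 0

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties to smallest (i, j)
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        i, j = min((int(a), int(b)) for a, b in ties if a < b)
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = D[i, j] - li
        if li < 0:
            li, clamped = 0.0, clamped + 1
        if lj < 0:
            lj, clamped = 0.0, clamped + 1
        nodes[i].length, nodes[j].length = float(li), float(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(k) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]

    # terminal 3-star: closed-form pendant lengths
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    for node, ln in zip(nodes, lens):
        if ln < 0:
            ln, clamped = 0.0, clamped + 1
        node.length = float(ln)
    root = TreeNode(children=nodes)
    root.n_clamped_branches = clamped
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree.

    Each internal edge is represented by the lexicographically smaller
    side of the leaf-name split, so rooted and unrooted layouts of the
    same topology yield identical sets.
    """
    all_leaves = frozenset(l.name for l in tree.tips())
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        out.add(frozenset(canon))
    return out


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson–Foulds distance (symmetric difference of bipartitions)."""
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


def bootstrap_support(
    msa: Msa,
    model: str = "K80",
    n_reps: int = 100,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with column-resampling bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; each
    replicate tree's bipartitions are counted and their frequencies (in
    percent) mapped onto the full-data tree as ``node.support``. With
    ``n_reps=0`` the tree is returned without supports and flagged.
    """
    full = nj_tree(distance_matrix(msa, model))
    if n_reps == 0:
        full.no_supports = True
        return full
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    ncol = msa.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep = Msa(seq_ids=list(msa.seq_ids), matrix=msa.matrix[:, cols])
        rep_tree = nj_tree(distance_matrix(rep, model))
        for bp in bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1

    all_leaves = frozenset(l.name for l in full.tips())
    for node in full.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            node.support = None
            continue
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        node.support = 100.0 * counts.get(frozenset(canon), 0) / n_reps
    full.no_supports = False
    return full


def root_with_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root on the outgroup's pendant edge (split at its midpoint)."""
    try:
        tree.find(outgroup)
    except Exception as exc:
        raise ValueError(f"outgroup {outgroup!r} not found in tree") from exc
    return tree.root_at(outgroup, above=True, branch_attrs=["support"])


def clade_of(
    tree: TreeNode,
    query: str,
    panel: ReferencePanel,
    min_support: float = 50.0,
) -> str | None:
    """Panel assignment of a query leaf in a rooted, supported tree.

    Finds the smallest clade containing the query whose support is at
    least ``min_support`` (the root always qualifies) and returns the
    target panel reference that is the query's closest leaf within it
    by patristic distance — or None when that clade contains no target
    reference.
    """
    leaf = tree.find(query)
    targets = {e.ref_id for e in panel.targets()}
    node = leaf.parent
    while node is not None:
        sup = getattr(node, "support", None)
        qualifies = node.is_root() or (sup is not None and sup >= min_support)
        if qualifies:
            cands = [t for t in node.tips() if t.name in targets]
            if not cands:
                return None
            best = min(cands, key=lambda t: (leaf.distance(t), t.name))
            return best.name
        node = node.parent
    return None


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write newick with bootstrap supports as internal node labels."""
    t = tree.copy()
    for node in t.non_tips(include_self=True):
        sup = getattr(node, "support", None)
        if sup is not None:
            node.name = f"{sup:.0f}"
    t.write(str(path))
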