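"""Median-joining haplotype networks.

Identical rows of a gap/N-free alignment are collapsed into haplotypes;
the network combines an epsilon-relaxed minimum-spanning network over
Hamming distances with inferred median haplotypes — the column-wise
majority of three mutually connected nodes — added whenever they
shorten the network, approximating a Steiner-minimal network. Median
nodes that end up with degree below three are pruned, and the whole
procedure iterates to a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from Bio.Nexus import Nexus

from .msa import Msa, _encode_row

__all__ = [
    "Haplotype",
    "HaploNetwork",
    "collapse_haplotypes",
    "build_mj_network",
    "read_nexus_alignment",
]


@dataclass(frozen=True)
class Haplotype:
    id: str
    states: tuple[int, ...]
    frequency: int
    member_ids: tuple[str, ...]


def collapse_haplotypes(msa: Msa) -> list[Haplotype]:
    """Merge identical alignment rows, counting their frequency.

    Haplotypes are ordered and named (H1, H2, ...) by first occurrence,
    so the collapse is deterministic in the input order of sequences.
    """
    if msa.n_seqs == 0 or msa.n_columns == 0:
        raise ValueError("empty alignment")
    if not msa.is_clean():
        raise ValueError("haplotype collapse requires a gap/N-free alignment")
    seen: dict[tuple[int, ...], list[str]] = {}
    order: list[tuple[int, ...]] = []
    for sid, row in zip(msa.seq_ids, msa.matrix):
        key = tuple(int(x) for x in row)
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(sid)
    return [
        Haplotype(id=f"H{i + 1}", states=key, frequency=len(seen[key]),
                  member_ids=tuple(seen[key]))
        for i, key in enumerate(order)
    ]


@dataclass
class HaploNetwork:
    """Sampled and inferred (median) haplotypes with mutation-weighted edges."""

    graph: nx.Graph = field(repr=False)
    haplotypes: list[Haplotype]
    medians: list[Haplotype]
    epsilon: int
    converged: bool = True

    @property
    def total_length(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def write_edges_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tmutations\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']}\n")

    def write_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(n, is_median=bool(d["is_median"]), frequency=int(d["frequency"]),
                       members=",".join(d.get("members", ())))
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, weight=int(d["weight"]))
        nx.write_graphml(g, str(path))


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def _dist_matrix(states: np.ndarray) -> np.ndarray:
    return (states[:, None, :] != states[None, :, :]).sum(axis=2)


def _msn_edges(D: np.ndarray, epsilon: int) -> list[tuple[int, int, int]]:
    """Epsilon-relaxed minimum-spanning network edges.

    A pair (u, v) is connected iff d(u, v) <= sigma(u, v) + epsilon,
    where sigma is the level at which u and v first join when merging
    whole distance levels in ascending order (the minimax path weight).
    """
    n = D.shape[0]
    if n == 1:
        return []
    levels = np.unique(D[np.triu_indices(n, 1)])
    comp = np.arange(n)
    sigma = np.zeros((n, n), dtype=np.int64)
    for lv in levels:
        before = comp.copy()
        for i in range(n):
            for j in range(i + 1, n):
                if D[i, j] == lv and comp[i] != comp[j]:
                    old, new = comp[j], comp[i]
                    comp[comp == old] = new
        newly = (before[:, None] != before[None, :]) & (comp[:, None] == comp[None, :])
        sigma[newly & (sigma == 0)] = lv
        if np.all(comp == comp[0]):
            # remaining unconnected-at-lower-level pairs already recorded
            break
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] <= sigma[i, j] + epsilon:
                edges.append((i, j, int(D[i, j])))
    return edges


def _mst_length(D: np.ndarray) -> int:
    """Total weight of a minimum spanning tree (Prim)."""
    n = D.shape[0]
    if n < 2:
        return 0
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = D[0].astype(np.int64).copy()
    total = 0
    for _ in range(n - 1):
        best_masked = np.where(in_tree, np.iinfo(np.int64).max, best)
        k = int(best_masked.argmin())
        total += int(best_masked[k])
        in_tree[k] = True
        best = np.minimum(best, D[k])
    return total


def _median_vector(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Column-wise majority of three state vectors.

    Where all three states differ the tie resolves to the first vector
    in the fixed node ordering, keeping the construction deterministic.
    """
    med = a.copy()
    eq_bc = b == c
    med[eq_bc] = b[eq_bc]  # b==c outvotes a (and agrees when all equal)
    return med


def build_mj_network(
    haplotypes: list[Haplotype],
    epsilon: int = 0,
    max_iter: int = 50,
) -> HaploNetwork:
    """Median-joining network construction.

    Iterates: (1) epsilon-relaxed minimum-spanning network over Hamming
    distances; (2) for every mutually connected triplet, propose the
    median vector and add it if it shortens the minimum spanning tree
    over the node set; (3) prune non-sampled nodes of degree < 3;
    repeat to a fixed point (cap ``max_iter``, which epsilon=0 data
    does not reach in practice).
    """
    if len(haplotypes) < 2:
        raise ValueError("need at least two haplotypes")
    ncol = len(haplotypes[0].states)
    if any(len(h.states) != ncol for h in haplotypes):
        raise ValueError("haplotypes have differing lengths")

    # canonical node ordering (lexicographic on state vectors) makes the
    # construction, including median tie-breaks, invariant to input order
    order = sorted(range(len(haplotypes)), key=lambda i: haplotypes[i].states)
    sorted_haps = [haplotypes[i] for i in order]
    states = [np.array(h.states, dtype=np.int16) for h in sorted_haps]
    is_median = [False] * len(states)
    median_serial = 0
    converged = False

    for _ in range(max_iter):
        arr = np.vstack(states)
        D = _dist_matrix(arr)
        edges = _msn_edges(D, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(states))}
        for i, j, _w in edges:
            adj[i].add(j)
            adj[j].add(i)

        # candidate medians from mutually connected triplets
        candidates: list[np.ndarray] = []
        seen_keys = {tuple(int(x) for x in s) for s in states}
        for i in range(len(states)):
            for j in sorted(adj[i]):
                if j <= i:
                    continue
                for k in sorted(adj[i] & adj[j]):
                    if k <= j:
                        continue
                    med = _median_vector(arr[i], arr[j], arr[k])
                    key = tuple(int(x) for x in med)
                    if key not in seen_keys:
                        seen_keys.add(key)
                        candidates.append(med)

        base_len = _mst_length(D)
        added = False
        for med in candidates:
            arr2 = np.vstack(states + [med])
            if _mst_length(_dist_matrix(arr2)) < base_len:
                states.append(med)
                is_median.append(True)
                added = True
                arr = np.vstack(states)
                D = _dist_matrix(arr)
                base_len = _mst_length(D)

        # prune obsolete medians (degree < 3 in the current MSN)
        pruned = False
        while True:
            arr = np.vstack(states)
            D = _dist_matrix(arr)
            deg = {i: 0 for i in range(len(states))}
            for i, j, _w in _msn_edges(D, epsilon):
                deg[i] += 1
                deg[j] += 1
            drop = [i for i in range(len(states)) if is_median[i] and deg[i] < 3]
            if not drop:
                break
            pruned = True
            states = [s for i, s in enumerate(states) if i not in drop]
            is_median = [m for i, m in enumerate(is_median) if i not in drop]

        if not added and not pruned:
            converged = True
            break

    # final graph
    arr = np.vstack(states)
    D = _dist_matrix(arr)
    names: list[str] = []
    medians: list[Haplotype] = []
    g = nx.Graph()
    si = 0
    for i, s in enumerate(states):
        if is_median[i]:
            median_serial += 1
            h = Haplotype(id=f"M{median_serial}", states=tuple(int(x) for x in s),
                          frequency=0, member_ids=())
            medians.append(h)
        else:
            h = sorted_haps[si]
            si += 1
        names.append(h.id)
        g.add_node(h.id, is_median=is_median[i], frequency=h.frequency,
                   members=h.member_ids)
    for i, j, w in _msn_edges(D, epsilon):
        g.add_edge(names[i], names[j], weight=w)

    return HaploNetwork(
        graph=g,
        haplotypes=list(haplotypes),
        medians=medians,
        epsilon=epsilon,
        converged=converged,
    )


def read_nexus_alignment(path: str | Path) -> Msa:
    """Read a NEXUS DATA/CHARACTERS block into an alignment."""
    nex = Nexus.Nexus(str(path))
    ids = list(nex.matrix.keys())
    rows = [_encode_row(str(nex.matrix[i])) for i in ids]
    return Msa(seq_ids=[str(i) for i in ids], matrix=np.vstack(rows))
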