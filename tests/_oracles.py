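"""Independent brute-force oracles used by the tests.

Everything here is deliberately written from first principles — plain loops
and explicit formulas — so it shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math


def site_counts_by_hand(a: str, b: str):
    """Transition/transversion proportions by explicit per-site comparison."""
    ts = tv = L = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        L += 1
        if x != y:
            if {x, y} in ({"A", "G"}, {"C", "T"}):
                ts += 1
            else:
                tv += 1
    return ts / L, tv / L, L


def tn93_by_hand(a: str, b: str) -> float:
    """Direct transcription of the published TN93 closed form."""
    pur_ts = pyr_ts = tv = L = 0
    base_counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        L += 1
        base_counts[x] += 1
        base_counts[y] += 1
        if x != y:
            if {x, y} == {"A", "G"}:
                pur_ts += 1
            elif {x, y} == {"C", "T"}:
                pyr_ts += 1
            else:
                tv += 1
    gA, gC, gG, gT = (base_counts[n] / (2 * L) for n in "ACGT")
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = pur_ts / L, pyr_ts / L, tv / L
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    return (
        -k1 * math.log(1 - P1 / k1 - Q / (2 * gR))
        - k2 * math.log(1 - P2 / k2 - Q / (2 * gY))
        - k3 * math.log(1 - Q / (2 * gR * gY))
    )


class UnrootedTree:
    """Minimal unrooted-tree graph for exhaustive topology enumeration."""

    def __init__(self):
        self.adj: dict[int, dict[int, float]] = {}
        self.labels: dict[int, str] = {}
        self._next = 0

    def _new_node(self, label=None) -> int:
        n = self._next
        self._next += 1
        self.adj[n] = {}
        if label is not None:
            self.labels[n] = label
        return n

    def _connect(self, u: int, v: int, length: float = 1.0) -> None:
        self.adj[u][v] = length
        self.adj[v][u] = length

    @classmethod
    def star3(cls, labels) -> "UnrootedTree":
        t = cls()
        center = t._new_node()
        for lab in labels:
            t._connect(center, t._new_node(lab))
        return t

    def edges(self):
        return [(u, v) for u in self.adj for v in self.adj[u] if u < v]

    def insert_leaf(self, edge, label) -> "UnrootedTree":
        """Copy of the tree with a new leaf attached inside the given edge."""
        import copy

        t = copy.deepcopy(self)
        u, v = edge
        del t.adj[u][v], t.adj[v][u]
        mid = t._new_node()
        t._connect(u, mid)
        t._connect(mid, v)
        t._connect(mid, t._new_node(label))
        return t

    def set_random_lengths(self, rng, lo=0.05, hi=1.0) -> None:
        for u, v in self.edges():
            ln = float(rng.uniform(lo, hi))
            self.adj[u][v] = ln
            self.adj[v][u] = ln

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """All leaf-to-leaf path lengths by breadth-first search."""
        out = {}
        leaves = {n: lab for n, lab in self.labels.items()}
        for src, src_lab in leaves.items():
            dist = {src: 0.0}
            queue = [src]
            while queue:
                cur = queue.pop(0)
                for nb, ln in self.adj[cur].items():
                    if nb not in dist:
                        dist[nb] = dist[cur] + ln
                        queue.append(nb)
            for dst, dst_lab in leaves.items():
                if src_lab < dst_lab:
                    out[(src_lab, dst_lab)] = dist[dst]
        return out

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions, normalized to exclude the smallest label."""
        all_labels = frozenset(self.labels.values())
        ref = min(all_labels)
        result = set()
        for u, v in self.edges():
            # component containing u with edge (u, v) removed
            seen = {u}
            queue = [u]
            while queue:
                cur = queue.pop(0)
                for nb in self.adj[cur]:
                    if (cur, nb) in ((u, v), (v, u)) or nb in seen:
                        continue
                    seen.add(nb)
                    queue.append(nb)
            side = frozenset(self.labels[n] for n in seen if n in self.labels)
            if ref in side:
                side = all_labels - side
            if 2 <= len(side) <= len(all_labels) - 2:
                result.add(side)
        return result


def all_unrooted_topologies(labels) -> list[UnrootedTree]:
    """Every labelled unrooted binary topology (3 for n=4, 15 for n=5)."""
    labels = list(labels)
    trees = [UnrootedTree.star3(labels[:3])]
    for lab in labels[3:]:
        trees = [t.insert_leaf(e, lab) for t in trees for e in t.edges()]
    return trees


def dendropy_splits(tree) -> set[frozenset[str]]:
    """Same normalization as UnrootedTree.splits, for a dendropy tree."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def dendropy_leaf_distances(tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    for t1, t2 in itertools.combinations(taxa, 2):
        out[(t1.label, t2.label)] = pdm.patristic_distance(t1, t2)
    return out
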