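"""Neighbor-joining trees, bootstrap supports and species-monophyly tests.

Trees are :class:`dendropy.Tree` objects (newick round-trips, rerooting and
traversal come with the container); the neighbor-joining agglomeration,
bootstrap resampling and monophyly logic are implemented here.

Neighbor joining (Saitou & Nei) is exact on additive distance matrices: path
lengths between leaves of the reconstructed tree reproduce the input
distances. Ties in the Q criterion are broken by the lowest (i, j) index pair
so the algorithm is deterministic; negative branch-length estimates are
clamped to zero with the deficit moved to the sister branch so leaf-to-leaf
paths are preserved.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np

from .errors import OutgroupError, ValidationError
from .moldist import DistanceMatrix, SpeciesAlignment, SubstModelParams, pairwise_matrix


def _new_tree(taxa: tuple[str, ...]) -> tuple[dendropy.Tree, dict[str, dendropy.Node]]:
    tns = dendropy.TaxonNamespace(list(taxa))
    tree = dendropy.Tree(taxon_namespace=tns)
    leaves = {}
    for label in taxa:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        leaves[label] = node
    return tree, leaves


def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a pairwise distance matrix.

    Returns an unrooted tree (trifurcating seed node for ≥ 3 taxa, a direct
    two-leaf split for 2 taxa). Undefined matrix cells are an error.
    """
    n = len(matrix.taxa)
    if n < 2:
        raise ValidationError("need at least two taxa to build a tree")
    off_diag = ~np.eye(n, dtype=bool)
    if np.isnan(matrix.values[off_diag]).any():
        bad = [
            (matrix.taxa[i], matrix.taxa[j])
            for i in range(n)
            for j in range(i + 1, n)
            if math.isnan(matrix.values[i, j])
        ]
        raise ValidationError(f"undefined distances for pairs: {bad}")

    tree, leaf_nodes = _new_tree(matrix.taxa)
    nodes: list[dendropy.Node] = [leaf_nodes[t] for t in matrix.taxa]
    lengths: dict[int, float] = {}  # id(node) -> branch length to its parent-to-be
    D = matrix.values.astype(float).copy()

    if n == 2:
        d = D[0, 1]
        _attach(tree.seed_node, nodes[0], d / 2.0)
        _attach(tree.seed_node, nodes[1], d / 2.0)
        return tree

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        # Q criterion; scan in index order so ties go to the lowest (i, j)
        best, best_q = None, math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best, best_q = (i, j), q
        i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)

        parent = dendropy.Node()
        _attach(parent, nodes[i], li)
        _attach(parent, nodes[j], lj)

        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_row[keep]])
        D = np.column_stack([D, np.append(new_row[keep], 0.0)])
        nodes = [nodes[k] for k in keep] + [parent]

    # final trifurcation: three-point formulas, clamped at zero
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max(0.0, 0.5 * (d01 + d02 - d12))
    l1 = max(0.0, 0.5 * (d01 + d12 - d02))
    l2 = max(0.0, 0.5 * (d02 + d12 - d01))
    for node, length in zip(nodes, (l0, l1, l2)):
        _attach(tree.seed_node, node, length)
    return tree


def _attach(parent: dendropy.Node, child: dendropy.Node, length: float) -> None:
    parent.add_child(child)
    child.edge.length = length


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sister."""
    total = li + lj
    if li < 0.0:
        return 0.0, total
    if lj < 0.0:
        return total, 0.0
    return li, lj


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial splits of an (un)rooted tree, as leaf sets normalized to
    exclude the lexicographically first taxon."""
    all_leaves = leaf_labels(tree)
    ref = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    alignment: SpeciesAlignment,
    model: str = "k2p",
    replicates: int = 100,
    seed: int = 0,
    *,
    deletion_policy: str = "pairwise",
    model_params: SubstModelParams | None = None,
    max_retries_per_replicate: int = 20,
) -> dendropy.Tree:
    """NJ tree with nonparametric bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement per replicate; the
    support of each internal edge of the point-estimate tree is the
    percentage of replicate trees containing the same bipartition, attached
    as an integer node label. A replicate whose resampled matrix has an
    undefined cell is redrawn, up to a bounded retry count. Deterministic
    for a fixed seed.
    """
    if replicates < 1:
        raise ValidationError("need at least one bootstrap replicate")
    point = nj_tree(
        pairwise_matrix(
            alignment, model, deletion_policy, model_params=model_params
        )
    )
    rng = np.random.default_rng(seed)
    L = alignment.length
    counts: dict[frozenset[str], int] = {s: 0 for s in bipartitions(point)}

    for _ in range(replicates):
        for attempt in range(max_retries_per_replicate + 1):
            cols = rng.integers(0, L, size=L)
            resampled = SpeciesAlignment(
                taxa=alignment.taxa,
                sequences=tuple(
                    "".join(s[c] for c in cols) for s in alignment.sequences
                ),
                species_map=alignment.species_map,
            )
            mat = pairwise_matrix(
                resampled, model, deletion_policy, model_params=model_params
            )
            if not np.isnan(mat.values).any():
                break
        else:
            raise ValidationError(
                f"bootstrap replicate undefined after {max_retries_per_replicate} retries"
            )
        for split in bipartitions(nj_tree(mat)):
            if split in counts:
                counts[split] += 1

    all_leaves = leaf_labels(point)
    ref = min(all_leaves)
    for node in point.preorder_node_iter():
        if node is point.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if side in counts:
            node.label = str(round(100.0 * counts[side] / replicates))
    return point


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree(tree)


def root_at_outgroup(tree: dendropy.Tree, outgroup_taxa: list[str]) -> dendropy.Tree:
    """Return a copy of the tree rooted on the edge separating the outgroup.

    The outgroup must form one side of an edge of the unrooted tree; a
    scattered (polyphyletic) outgroup is an error.
    """
    if not outgroup_taxa:
        raise OutgroupError("no outgroup taxa given")
    all_leaves = leaf_labels(tree)
    missing = [t for t in outgroup_taxa if t not in all_leaves]
    if missing:
        raise OutgroupError(f"outgroup taxa not in tree: {missing}")
    og = frozenset(outgroup_taxa)
    if len(og) >= len(all_leaves):
        raise OutgroupError("outgroup contains every leaf")

    rooted = _clone(tree)
    target = None
    for node in rooted.preorder_node_iter():
        if node is rooted.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if side == og or (all_leaves - side) == og:
            target = node
            break
    if target is None:
        raise OutgroupError(
            f"outgroup {sorted(og)} is not a clade of the unrooted tree"
        )
    length = target.edge.length or 0.0
    rooted.reroot_at_edge(target.edge, length1=length / 2.0, length2=length / 2.0)
    rooted.is_rooted = True
    return rooted


def is_monophyletic(
    tree: dendropy.Tree,
    species_map: dict[str, str],
    species_label: str,
    outgroup_taxa: list[str],
) -> bool:
    """Is a species monophyletic after rooting the tree on the outgroup?

    True iff the smallest rooted clade containing every leaf of the species
    contains no other leaves. A single-member species is monophyletic by
    definition.
    """
    members = [
        leaf
        for leaf in leaf_labels(tree)
        if species_map.get(leaf) == species_label
    ]
    if not members:
        raise ValidationError(f"species {species_label!r} has no leaves in the tree")
    if len(members) == 1:
        return True
    rooted = root_at_outgroup(tree, outgroup_taxa)
    mrca = rooted.mrca(taxon_labels=members)
    clade = frozenset(leaf.taxon.label for leaf in mrca.leaf_iter())
    return clade == frozenset(members)


def monophyly_report(
    tree: dendropy.Tree,
    species_map: dict[str, str],
    outgroup_taxa: list[str],
) -> dict[str, bool]:
    """Monophyly verdict for every non-outgroup species in the tree."""
    og = set(outgroup_taxa)
    species = sorted(
        {species_map[t] for t in leaf_labels(tree) if t in species_map and t not in og}
    )
    return {
        s: is_monophyletic(tree, species_map, s, outgroup_taxa) for s in species
    }
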