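"""Neighbor joining, bootstrap supports and monophyly testing."""

import math

import dendropy
import numpy as np
import pytest

from _oracles import all_unrooted_topologies, dendropy_leaf_distances, dendropy_splits
from karyocoi import (
    DistanceMatrix,
    OutgroupError,
    ValidationError,
    bootstrap_support,
    is_monophyletic,
    monophyly_report,
    nj_tree,
    root_at_outgroup,
)
from karyocoi.simulate import SeqSimConfig, simulate_alignment
from karyocoi.moldist import SubstModelParams


def _matrix(taxa, dist):
    n = len(taxa)
    vals = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                key = (a, b) if (a, b) in dist else (b, a)
                vals[i, j] = vals[j, i] = dist[key]
    return DistanceMatrix(taxa=tuple(taxa), values=vals)


def test_three_taxon_closed_form():
    """d(A,B)=0.2, d(A,C)=0.3, d(B,C)=0.4 → terminal branches .05/.15/.25."""
    m = _matrix(("A", "B", "C"), {("A", "B"): 0.2, ("A", "C"): 0.3, ("B", "C"): 0.4})
    tree = nj_tree(m)
    lengths = {
        leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
    }
    assert lengths["A"] == pytest.approx(0.05)
    assert lengths["B"] == pytest.approx(0.15)
    assert lengths["C"] == pytest.approx(0.25)


def test_two_taxa_single_split():
    m = _matrix(("A", "B"), {("A", "B"): 0.3})
    tree = nj_tree(m)
    d = dendropy_leaf_distances(tree)[("A", "B")]
    assert d == pytest.approx(0.3)


@pytest.mark.parametrize("n_taxa,n_expected", [(4, 3), (5, 15)])
def test_nj_exact_on_all_additive_topologies(n_taxa, n_expected):
    """NJ recovers every labelled unrooted topology from its additive matrix,
    with leaf-to-leaf path lengths reproduced to 1e-9."""
    labels = list("ABCDE")[:n_taxa]
    topologies = all_unrooted_topologies(labels)
    assert len(topologies) == n_expected
    assert len({frozenset(t.splits()) for t in topologies}) == n_expected
    rng = np.random.default_rng(7)
    for topo in topologies:
        topo.set_random_lengths(rng)
        dist = topo.leaf_distances()
        tree = nj_tree(_matrix(labels, dist))
        assert dendropy_splits(tree) == topo.splits()
        recovered = dendropy_leaf_distances(tree)
        for pair, d in dist.items():
            assert recovered[pair] == pytest.approx(d, abs=1e-9)


def test_nj_agrees_with_dendropy_reference():
    """Independent cross-check on a well-separated additive matrix: our NJ
    and dendropy's NJ both recover the generating topology."""
    from _oracles import all_unrooted_topologies

    topo = all_unrooted_topologies(list("ABCDEF")[:6])[7]
    topo.set_random_lengths(np.random.default_rng(23), lo=0.1, hi=0.9)
    dist = topo.leaf_distances()
    labels = sorted({x for pair in dist for x in pair})
    matrix = _matrix(labels, dist)
    ours = dendropy_splits(nj_tree(matrix))
    csv_rows = ["," + ",".join(matrix.taxa)]
    for i, t in enumerate(matrix.taxa):
        csv_rows.append(t + "," + ",".join(str(x) for x in matrix.values[i]))
    import io as _io

    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=_io.StringIO("\n".join(csv_rows)), delimiter=","
    )
    theirs = dendropy_splits(pdm.nj_tree())
    assert ours == theirs == topo.splits()


def test_equidistant_matrix_deterministic():
    taxa = ("A", "B", "C", "D")
    vals = np.full((4, 4), 0.5)
    np.fill_diagonal(vals, 0.0)
    m = DistanceMatrix(taxa=taxa, values=vals)
    t1 = nj_tree(m).as_string(schema="newick")
    t2 = nj_tree(m).as_string(schema="newick")
    assert t1 == t2  # lowest-(i,j) tie-break makes the result reproducible


def test_nj_rejects_undefined_cells():
    vals = np.array([[0, 0.1, math.nan], [0.1, 0, 0.2], [math.nan, 0.2, 0]])
    with pytest.raises(ValidationError, match="undefined"):
        nj_tree(DistanceMatrix(taxa=("A", "B", "C"), values=vals))


def test_negative_branch_clamped_preserving_paths():
    """A slightly non-additive matrix may imply a negative branch; it is
    clamped to zero and the deficit moved to the sister, so no length < 0."""
    taxa = ("A", "B", "C", "D")
    dist = {
        ("A", "B"): 0.01, ("A", "C"): 0.30, ("A", "D"): 0.31,
        ("B", "C"): 0.29, ("B", "D"): 0.32, ("C", "D"): 0.01,
    }
    tree = nj_tree(_matrix(taxa, dist))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            assert edge.length >= 0.0


def _two_clade_alignment(seed=0):
    # two internally identical clades separated by strong divergence
    tree = "((A1:0.0,A2:0.0,A3:0.0):0.2,(B1:0.0,B2:0.0,B3:0.0):0.2);"
    cfg = SeqSimConfig(
        tree=tree,
        model=SubstModelParams(gamma_shape=None),
        length=600,
        seed=seed,
    )
    return simulate_alignment(cfg)


def test_bootstrap_overwhelming_signal_high_support():
    aln = _two_clade_alignment()
    tree = bootstrap_support(aln, replicates=100, seed=3)
    supports = [
        int(n.label)
        for n in tree.preorder_node_iter()
        if n.label is not None and not n.is_leaf()
    ]
    assert supports and all(s >= 99 for s in supports)


def test_bootstrap_single_replicate_and_determinism():
    aln = _two_clade_alignment(seed=5)
    t1 = bootstrap_support(aln, replicates=1, seed=9)
    sup1 = sorted(
        n.label for n in t1.preorder_node_iter() if n.label and not n.is_leaf()
    )
    assert set(sup1) <= {"0", "100"}
    t2 = bootstrap_support(aln, replicates=1, seed=9)
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


SPECIES = {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "O": "OUT"}


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def test_monophyly_true_and_false_cases():
    good = _tree("(((A1:1,A2:1):1,(B1:1,B2:1):1):1,O:3);")
    assert is_monophyletic(good, SPECIES, "A", ["O"]) is True
    assert is_monophyletic(good, SPECIES, "B", ["O"]) is True
    mixed = _tree("(((A1:1,B1:1):1,(A2:1,B2:1):1):1,O:3);")
    assert is_monophyletic(mixed, SPECIES, "A", ["O"]) is False
    assert monophyly_report(mixed, SPECIES, ["O"]) == {"A": False, "B": False}


def test_single_member_species_trivially_monophyletic():
    tree = _tree("((A1:1,(B1:1,B2:1):1):1,O:3);")
    assert is_monophyletic(tree, SPECIES, "A", ["O"]) is True


def test_missing_outgroup_errors():
    tree = _tree("((A1:1,A2:1):1,B1:2);")
    with pytest.raises(OutgroupError, match="not in tree"):
        is_monophyletic(tree, SPECIES, "A", ["O"])


def test_scattered_outgroup_errors():
    tree = _tree("((A1:1,O1:1):1,(A2:1,O2:1):1);")
    species = {"A1": "A", "A2": "A", "O1": "OUT", "O2": "OUT"}
    with pytest.raises(OutgroupError, match="not a clade"):
        root_at_outgroup(tree, ["O1", "O2"])


def test_newick_round_trip_preserves_everything(tmp_path):
    from karyocoi import io

    newick = "((A1:0.1,A2:0.2)95:0.05,(B1:0.1,B2:0.3)88:0.07,O:0.5);"
    tree = _tree(newick)
    path = tmp_path / "t.nwk"
    io.write_newick(path, tree)
    back = io.read_newick(path)
    assert dendropy_splits(back) == dendropy_splits(tree)
    assert dendropy_leaf_distances(back) == pytest.approx(
        dendropy_leaf_distances(tree)
    )
    labels = sorted(
        n.label for n in back.preorder_node_iter() if n.label and not n.is_leaf()
    )
    assert labels == ["88", "95"]
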