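"""Site-pattern counting and the K2P / TN93 / gamma distance formulas."""

import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from _oracles import site_counts_by_hand, tn93_by_hand
from karyocoi import (
    NoOverlapError,
    SiteCounts,
    SpeciesAlignment,
    SubstModelParams,
    ValidationError,
    count_site_patterns,
    gamma_corrected_distance,
    group_mean_distance,
    k2p_distance,
    p_distance,
    pairwise_matrix,
    tn93_distance,
)


@pytest.mark.parametrize(
    "a,b,P,Q,L",
    [
        ("ACGT", "ACGT", 0.0, 0.0, 4),
        ("ACGT", "GCGT", 0.25, 0.0, 4),  # A→G is a transition
        ("AC-T", "ACGT", 0.0, 0.0, 3),  # gapped site dropped
        ("ACNT", "ACGT", 0.0, 0.0, 3),  # N excluded like a gap
        ("ACGT", "ATGT", 0.25, 0.0, 4),  # C→T transition
        ("ACGT", "CCGT", 0.0, 0.25, 4),  # A→C transversion
    ],
)
def test_count_site_patterns(a, b, P, Q, L):
    c = count_site_patterns(a, b)
    assert (c.P, c.Q, c.L) == (P, Q, L)


def test_no_overlap_is_an_error():
    with pytest.raises(NoOverlapError):
        count_site_patterns("--AC", "GT--")


def test_unequal_lengths_rejected():
    with pytest.raises(ValidationError):
        count_site_patterns("ACGT", "ACG")


def test_k2p_closed_form_example():
    """P=0.1, Q=0.05 → −½ ln(0.75·√0.9), evaluated independently."""
    c = SiteCounts(P=0.1, Q=0.05, L=600)
    expected = -0.5 * math.log(0.75 * math.sqrt(0.9))
    assert k2p_distance(c) == pytest.approx(expected, abs=1e-12)
    assert k2p_distance(c) == pytest.approx(0.1702, abs=5e-5)


def test_k2p_zero_and_saturated():
    assert k2p_distance(SiteCounts(P=0.0, Q=0.0, L=100)) == 0.0
    assert math.isnan(k2p_distance(SiteCounts(P=0.5, Q=0.0, L=100)))


@given(
    st.floats(min_value=0.0, max_value=0.4),
    st.floats(min_value=0.0, max_value=0.4),
)
def test_k2p_dominates_p_distance(P, Q):
    """The multiple-hit correction can only increase the distance."""
    assume(1 - 2 * P - Q > 1e-6 and 1 - 2 * Q > 1e-6)
    c = SiteCounts(P=P, Q=Q, L=1000)
    d = k2p_distance(c)
    if P + Q == 0:
        assert d == 0.0
    else:
        assert d > p_distance(c) - 1e-15


@given(
    st.floats(min_value=0.0, max_value=0.3),
    st.floats(min_value=0.0, max_value=0.3),
)
def test_tn93_reduces_to_k2p_under_symmetry(P, Q):
    """Uniform frequencies + equal transition split collapse TN93 to K2P."""
    assume(1 - 2 * P - Q > 1e-6 and 1 - 2 * Q > 1e-6)
    c = SiteCounts(
        P=P, Q=Q, L=1000, p_purine=P / 2, p_pyrimidine=P / 2,
        base_freqs=(0.25, 0.25, 0.25, 0.25),
    )
    assert tn93_distance(c) == pytest.approx(k2p_distance(c), abs=1e-9)


def test_tn93_matches_independent_formula_on_random_pair():
    """600-site random pair: package TN93 equals the hand-transcribed form."""
    rng = np.random.default_rng(42)
    bases = "ACGT"
    a = "".join(rng.choice(list(bases), p=[0.3, 0.2, 0.2, 0.3]) for _ in range(600))
    b = list(a)
    idx = rng.choice(600, size=60, replace=False)
    for i in idx:
        b[i] = bases[(bases.index(b[i]) + int(rng.integers(1, 4))) % 4]
    b = "".join(b)
    c = count_site_patterns(a, b)
    assert tn93_distance(c) == pytest.approx(tn93_by_hand(a, b), abs=1e-12)


def test_gamma_distance_zero_and_limit():
    model_inf = SubstModelParams(gamma_shape=1e6)
    zero = SiteCounts(P=0.0, Q=0.0, L=100)
    assert gamma_corrected_distance(zero, model_inf) == 0.0
    c = SiteCounts(P=0.1, Q=0.05, L=600)
    assert gamma_corrected_distance(c, model_inf) == pytest.approx(
        k2p_distance(c), abs=1e-4
    )


def test_gamma_distance_reported_shape_oracle():
    """α = 0.4292: high-precision evaluation of the closed form."""
    c = SiteCounts(P=0.1, Q=0.05, L=600)
    alpha = 0.4292
    expected = 0.5 * alpha * (0.75 ** (-1 / alpha) - 1) + 0.25 * alpha * (
        0.9 ** (-1 / alpha) - 1
    )
    assert gamma_corrected_distance(
        c, SubstModelParams(gamma_shape=alpha)
    ) == pytest.approx(expected, abs=1e-12)


@given(st.floats(min_value=0.2, max_value=100.0))
def test_gamma_correction_increases_distance(alpha):
    c = SiteCounts(P=0.08, Q=0.04, L=600)
    d_gamma = gamma_corrected_distance(c, SubstModelParams(gamma_shape=alpha))
    assert d_gamma > k2p_distance(c)


def test_pairwise_matrix_identical_sequences():
    aln = SpeciesAlignment(
        taxa=("a", "b"), sequences=("ACGT", "ACGT"), species_map={"a": "A", "b": "A"}
    )
    m = pairwise_matrix(aln)
    assert np.allclose(m.values, 0.0)


def test_pairwise_matrix_toy_alignment_hand_values(toy_alignment):
    """All six cells equal hand-counted P/Q pushed through the closed form."""
    m = pairwise_matrix(toy_alignment, "k2p")
    expected = {
        ("t1", "t2"): 0.05268025782891314,
        ("t1", "t3"): 0.1084661456574656,
        ("t1", "t4"): 0.05268025782891314,
        ("t2", "t3"): 0.1673576634856573,
        ("t2", "t4"): 0.11157177565710485,
        ("t3", "t4"): 0.1673576634856573,
    }
    for (a, b), d in expected.items():
        assert m.get(a, b) == pytest.approx(d, abs=1e-12)
        assert m.get(b, a) == pytest.approx(d, abs=1e-12)
    # and the hand counts themselves agree with the package counter
    for (a, b) in expected:
        sa = toy_alignment.sequences[toy_alignment.taxa.index(a)]
        sb = toy_alignment.sequences[toy_alignment.taxa.index(b)]
        P, Q, L = site_counts_by_hand(sa, sb)
        c = count_site_patterns(sa, sb)
        assert (c.P, c.Q, c.L) == (P, Q, L)


def test_matrix_symmetric_under_taxon_permutation(toy_alignment):
    perm = (2, 0, 3, 1)
    shuffled = SpeciesAlignment(
        taxa=tuple(toy_alignment.taxa[i] for i in perm),
        sequences=tuple(toy_alignment.sequences[i] for i in perm),
        species_map=toy_alignment.species_map,
    )
    m1 = pairwise_matrix(toy_alignment)
    m2 = pairwise_matrix(shuffled)
    for a in toy_alignment.taxa:
        for b in toy_alignment.taxa:
            assert m1.get(a, b) == pytest.approx(m2.get(a, b), abs=1e-15)


def test_saturated_pair_flagged_not_raised():
    aln = SpeciesAlignment(
        taxa=("a", "b"),
        sequences=("AAAA", "GGGG"),  # P = 1: far beyond the log domain
        species_map={"a": "A", "b": "B"},
    )
    m = pairwise_matrix(aln)
    assert math.isnan(m.get("a", "b"))
    assert not m.defined[0, 1]


def test_deletion_policies_change_compared_sites():
    # column 0 has 2/3 coverage: kept under pairwise, cut under complete/coverage
    aln = SpeciesAlignment(
        taxa=("a", "b", "c"),
        sequences=("-CGTACGTAC", "ACGTACGTAC", "ACGTACGTAC"),
        species_map={t: t for t in ("a", "b", "c")},
    )
    full = pairwise_matrix(aln, "p", "pairwise")
    comp = pairwise_matrix(aln, "p", "complete")
    cov = pairwise_matrix(aln, "p", "coverage", coverage=0.95)
    assert np.allclose(full.values, 0.0)
    assert np.allclose(comp.values, 0.0)
    assert np.allclose(cov.values, 0.0)
    assert count_site_patterns(aln.sequences[0], aln.sequences[1]).L == 9


def test_group_mean_distance_arithmetic():
    """A={a1,a2}, B={b1}, d=0.1/0.3 → between-mean 0.2."""
    vals = np.array(
        [[0.0, 0.02, 0.1], [0.02, 0.0, 0.3], [0.1, 0.3, 0.0]]
    )
    from karyocoi import DistanceMatrix

    m = DistanceMatrix(taxa=("a1", "a2", "b1"), values=vals)
    between, within = group_mean_distance(
        m, {"a1": "A", "a2": "A", "b1": "B"}
    )
    assert between.loc["A", "B"] == pytest.approx(0.2)
    assert within["A"] == pytest.approx(0.02)
    assert math.isnan(within["B"])


def test_group_mean_reports_undefined_pairs():
    from karyocoi import DistanceMatrix

    vals = np.array([[0.0, math.nan], [math.nan, 0.0]])
    m = DistanceMatrix(taxa=("a1", "b1"), values=vals)
    with pytest.raises(ValidationError, match="a1.*b1"):
        group_mean_distance(m, {"a1": "A", "b1": "B"})


def test_alignment_validation():
    with pytest.raises(ValidationError, match="unequal"):
        SpeciesAlignment(("a", "b"), ("ACGT", "ACG"), {"a": "A", "b": "B"})
    with pytest.raises(ValidationError, match="missing"):
        SpeciesAlignment(("a", "b"), ("ACGT", "ACGT"), {"a": "A"})
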