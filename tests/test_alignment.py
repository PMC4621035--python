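"""Contact-area scoring identities, similarity-field construction, and the
iterative-DP optimiser, against independent scalar-loop oracles."""

import numpy as np
import pytest

import cabalign as cb
from cabalign.config import CabParams
from cabalign.surface import ContactAreaMatrix
from cabalign.types import Alignment


def _cm(matrix):
    a = np.asarray(matrix, dtype=float)
    return ContactAreaMatrix(a=a)


def oracle_score(aln, cmA, cmB, gamma=0.5):
    """Independent scalar double loop over all ordered pairs."""
    total = 0.0
    for i in aln.as_tuples():
        for j in aln.as_tuples():
            dA, dB = abs(i[0] - j[0]), abs(i[1] - j[1])
            if dA <= 1 or dB <= 1:
                w = 0.0
            elif dA >= 5 and dB >= 5:
                w = 1.0
            else:
                w = gamma
            aA = cmA.a[i[0], j[0]]
            aB = cmB.a[i[1], j[1]]
            d = abs(aA - aB)
            total += w * (max(0.0, aA - d) + max(0.0, aB - d))
    return total


# ------------------------------------------------------------ pair weight

@pytest.mark.parametrize("i,j,expected", [
    ((3, 3), (3, 3), 0.0),        # i == j
    ((0, 0), (1, 5), 0.0),        # separation 1 in A
    ((0, 0), (7, 6), 1.0),        # both >= 5
    ((0, 0), (3, 8), 0.5),        # intermediate -> gamma
    ((0, 0), (8, 3), 0.5),
    ((0, 0), (4, 4), 0.5),
    ((0, 0), (5, 5), 1.0),
    ((0, 0), (2, 1), 0.0),        # separation 1 in B
])
def test_pair_weight_branch_table(i, j, expected):
    assert cb.pair_weight(i, j, gamma=0.5) == expected


# ----------------------------------------------------------------- theta

def test_theta_equal_areas_scores_twice_the_area():
    cmA = _cm([[0, 10], [10, 0]])
    cmB = _cm([[0, 10], [10, 0]])
    # use far-apart indices so w = 1 via a bigger matrix
    a = np.zeros((10, 10)); a[0, 7] = a[7, 0] = 10.0
    assert cb.theta((0, 0), (7, 7), _cm(a), _cm(a)) == pytest.approx(20.0)


def test_theta_missing_contact_scores_zero():
    a = np.zeros((10, 10)); a[0, 7] = a[7, 0] = 10.0
    b = np.zeros((10, 10))
    assert cb.theta((0, 0), (7, 7), _cm(a), _cm(b)) == 0.0


def test_theta_overprediction_still_scores():
    a = np.zeros((10, 10)); a[0, 7] = a[7, 0] = 10.0
    b = np.zeros((10, 10)); b[0, 7] = b[7, 0] = 4.0
    # d = 6: max(0, 10-6) + max(0, 4-6) = 4
    assert cb.theta((0, 0), (7, 7), _cm(a), _cm(b)) == pytest.approx(4.0)


def test_theta_symmetric_under_protein_swap(cm20, cm40):
    rng = np.random.default_rng(2)
    for _ in range(20):
        iA, jA = rng.integers(0, cm20.n, 2)
        iB, jB = rng.integers(0, cm40.n, 2)
        fwd = cb.theta((iA, iB), (jA, jB), cm20, cm40)
        rev = cb.theta((iB, iA), (jB, jA), cm40, cm20)
        assert fwd == pytest.approx(rev)


def test_theta_bounded_by_weighted_area_sum(cm20):
    rng = np.random.default_rng(3)
    for _ in range(50):
        iA, jA, iB, jB = rng.integers(0, cm20.n, 4)
        t = cb.theta((iA, iB), (jA, jB), cm20, cm20)
        w = cb.pair_weight((iA, iB), (jA, jB))
        assert 0.0 <= t <= w * (cm20.a[iA, jA] + cm20.a[iB, jB]) + 1e-12


# --------------------------------------------------------------- score S

def test_score_empty_alignment_is_zero(cm20):
    assert cb.alignment_score_S(Alignment.empty(), cm20, cm20) == 0.0


def test_score_matches_double_loop_oracle(cm20, cm40):
    ident = Alignment.identity(cm20.n)
    assert cb.alignment_score_S(ident, cm20, cm20) \
        == pytest.approx(oracle_score(ident, cm20, cm20))
    rng = np.random.default_rng(7)
    rows = np.sort(rng.choice(cm20.n, 12, replace=False))
    cols = np.sort(rng.choice(cm40.n, 12, replace=False))
    aln = Alignment(np.column_stack([rows, cols]))
    assert cb.alignment_score_S(aln, cm20, cm40) \
        == pytest.approx(oracle_score(aln, cm20, cm40))


def test_score_symmetric_under_protein_swap(cm20, cm40):
    rng = np.random.default_rng(8)
    rows = np.sort(rng.choice(cm20.n, 10, replace=False))
    cols = np.sort(rng.choice(cm40.n, 10, replace=False))
    aln = Alignment(np.column_stack([rows, cols]))
    swapped = Alignment(np.column_stack([cols, rows]))
    assert cb.alignment_score_S(aln, cm20, cm40) \
        == pytest.approx(cb.alignment_score_S(swapped, cm40, cm20))


# --------------------------------------------------------------- build_M

def test_build_M_empty_alignment_is_zero(cm20):
    assert not cb.build_M(Alignment.empty(), cm20, cm20).any()


def test_build_M_matches_exhaustive_pair_oracle(cm20, cm40):
    """M(k) must sum theta(i, k) over non-conflicting aligned i only,
    recomputed here cell by cell with scalar loops."""
    rng = np.random.default_rng(9)
    rows = np.sort(rng.choice(cm20.n, 6, replace=False))
    cols = np.sort(rng.choice(cm40.n, 6, replace=False))
    aln = Alignment(np.column_stack([rows, cols]))
    M = cb.build_M(aln, cm20, cm40)
    for kA in range(cm20.n):
        for kB in range(cm40.n):
            expected = sum(
                cb.theta((iA, iB), (kA, kB), cm20, cm40)
                for iA, iB in aln.as_tuples()
                if (kA - iA) * (kB - iB) > 0)
            assert M[kA, kB] == pytest.approx(expected)


def test_build_M_excludes_cell_at_aligned_pair():
    """At k equal to an aligned pair the product (kA-iA)(kB-iB) is zero, so
    that pair contributes nothing to its own cell."""
    a = np.zeros((8, 8))
    a[0, 4] = a[4, 0] = 20.0
    cm = _cm(a)
    aln = Alignment([(0, 0), (4, 4)])
    M = cb.build_M(aln, cm, cm)
    # cell (4, 4): only i = (0, 0) may contribute
    expected = cb.theta((0, 0), (4, 4), cm, cm)
    assert M[4, 4] == pytest.approx(expected)
    # and the conflicting quadrant gets nothing from (0, 0)
    assert M[0, 5] == 0.0


# --------------------------------------------------------------- smooth_M

def test_smooth_window_zero_is_identity():
    rng = np.random.default_rng(10)
    M = rng.uniform(size=(6, 7))
    assert np.array_equal(cb.smooth_M(M, 0), M)


def test_smooth_interior_cell_is_mean_of_three():
    rng = np.random.default_rng(11)
    M = rng.uniform(size=(5, 5))
    Mp = cb.smooth_M(M, 1)
    assert Mp[2, 2] == pytest.approx((M[1, 1] + M[2, 2] + M[3, 3]) / 3)


def test_smooth_corner_down_weighted():
    rng = np.random.default_rng(12)
    M = rng.uniform(size=(5, 5))
    Mp = cb.smooth_M(M, 1)
    # corner misses the (-1, -1) term but still divides by 3
    assert Mp[0, 0] == pytest.approx((M[0, 0] + M[1, 1]) / 3)
    assert Mp[4, 4] == pytest.approx((M[3, 3] + M[4, 4]) / 3)


# -------------------------------------------------------------- iterate_dp

def test_iterate_identity_self_alignment_fixed_point(cm20):
    ident = Alignment.identity(cm20.n)
    out = cb.iterate_dp(ident, cm20, cm20)
    assert out.alignment == ident
    assert out.S == pytest.approx(cb.alignment_score_S(ident, cm20, cm20))


def test_iterate_never_scores_below_seed(cm20, cm40):
    rng = np.random.default_rng(13)
    for _ in range(5):
        k = rng.integers(3, 10)
        rows = np.sort(rng.choice(cm20.n, k, replace=False))
        cols = np.sort(rng.choice(cm40.n, k, replace=False))
        seed = Alignment(np.column_stack([rows, cols]))
        out = cb.iterate_dp(seed, cm20, cm40)
        assert out.S >= cb.alignment_score_S(seed, cm20, cm40) - 1e-9


def test_iterate_extends_one_domain_seed_across_hinge(hinge_pair,
                                                      hinge_matrices):
    """From a seed covering only the first domain, iterative DP must walk
    across the linker and align both domains of the hinge-bent pair."""
    A, _B = hinge_pair
    cmA, cmB = hinge_matrices
    seed = Alignment([(i, i) for i in range(14)])
    out = cb.iterate_dp(seed, cmA, cmB)
    identical = sum(1 for a, b in out.alignment.as_tuples() if a == b)
    assert identical >= 0.9 * len(A)


# ------------------------------------------------------------------ dedupe

def test_dedupe_keeps_first_occurrence():
    x = Alignment([(0, 0), (1, 1)])
    y = Alignment([(0, 1), (1, 2)])
    assert cb.dedupe([x, Alignment([(0, 0), (1, 1)]), y]) == [x, y]
    assert cb.dedupe([x, y]) == [x, y]


def test_dedupe_shrinks_self_seed_set(helix20):
    seeds = cb.seed_set(helix20, helix20)
    assert len(cb.dedupe(seeds)) < 580


# ------------------------------------------------------------------ norm_s

def test_norm_s_closed_forms():
    assert cb.norm_s(0.0, 100.0, 200.0) == 0.0
    T = 2000.0
    assert cb.norm_s(1000.0, T, T, pow=0.7) \
        == pytest.approx(2 * 1000.0 / T ** 0.7)
    # independent exponentiation via logs
    import math
    expected = 1000.0 * math.exp(-0.7 * math.log(2000.0)) * 2
    assert cb.norm_s(1000.0, 2000.0, 2000.0, 0.7) == pytest.approx(expected)


def test_norm_s_rejects_degenerate_totals():
    with pytest.raises(ValueError):
        cb.norm_s(10.0, 0.0, 5.0)


# ---------------------------------------------------------------- cab_align

def test_cab_align_requires_seven_residues():
    short = cb.ChainStructure("A", cb.make_ideal_helix(10).residues[:5])
    with pytest.raises(ValueError):
        cb.cab_align(short, cb.make_ideal_helix(10))


def test_cab_align_symmetric_and_deterministic(hinge_pair, hinge_matrices):
    A, B = hinge_pair
    cmA, cmB = hinge_matrices
    fwd = cb.cab_align(A, B, cmA=cmA, cmB=cmB)
    rev = cb.cab_align(B, A, cmA=cmB, cmB=cmA)
    again = cb.cab_align(A, B, cmA=cmA, cmB=cmB)
    assert fwd.S == pytest.approx(rev.S, abs=1e-6)
    assert again.alignment == fwd.alignment and again.S == fwd.S


def test_cab_align_flexibility_score_near_self_score(hinge_pair,
                                                     hinge_matrices):
    """Hinge motion barely changes the contact matrices, so the cross-
    conformer S must be within 10% of the self-alignment S — similarity is
    carried by the contacts, not the coordinates."""
    A, B = hinge_pair
    cmA, cmB = hinge_matrices
    assert np.abs(cmA.a - cmB.a).sum() / 2 < 0.05 * cmA.total_area
    cross = cb.cab_align(A, B, cmA=cmA, cmB=cmB)
    self_s = cb.alignment_score_S(Alignment.identity(len(A)), cmA, cmA)
    assert cross.S >= 0.9 * self_s
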