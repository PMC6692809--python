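"""Diversity, FST, Tajima's D and ordination statistics."""

import itertools
import math

import numpy as np
import pytest

import chloropop as cp
from chloropop.variant_io import MISSING, PopulationMap

from conftest import make_matrix


def brute_force_pi(calls: np.ndarray, length: int) -> float:
    """Mean pairwise Hamming distance per site (complete data only)."""
    n = calls.shape[1]
    pairs = list(itertools.combinations(range(n), 2))
    total = sum(np.sum(calls[:, i] != calls[:, j]) for i, j in pairs)
    return total / len(pairs) / length


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def test_pi_zero_for_identical_sequences():
    m = make_matrix(np.ones((5, 4), dtype=int), genome_length=3000)
    wins = cp.nucleotide_diversity(m, window=1000, step=500)
    assert all(w.pi == 0.0 for w in wins)


def test_pi_two_sequences_single_difference():
    # one difference between 2 sequences in a 1000-bp window -> pi = 1/1000
    m = make_matrix([[0, 1]], positions=[500], genome_length=1000)
    wins = cp.nucleotide_diversity(m, window=1000, step=500)
    assert len(wins) == 1
    assert wins[0].pi == pytest.approx(0.001, abs=1e-15)


def test_pi_matches_pairwise_oracle_on_random_matrices():
    rng = np.random.default_rng(11)
    for _ in range(25):
        n, s = rng.integers(2, 13), rng.integers(1, 51)
        calls = rng.integers(0, 2, size=(s, n))
        m = make_matrix(calls, positions=list(range(1, s + 1)),
                        genome_length=2000)
        wins = cp.nucleotide_diversity(m, window=2000, step=2000)
        assert wins[0].pi == pytest.approx(brute_force_pi(calls, 2000),
                                           abs=1e-12)


def test_pi_windows_tile_genome_with_true_terminal_length():
    m = make_matrix(np.tile([0, 1], (3, 2)), positions=[10, 600, 1200],
                    genome_length=1250)
    wins = cp.nucleotide_diversity(m, window=1000, step=500)
    assert wins[0].start == 1 and wins[0].end == 1000
    assert wins[-1].end == 1250
    assert wins[-1].length == 1250 - wins[-1].start + 1


def test_pi_missing_data_uses_per_site_denominator():
    # site with calls [0, 1, MISSING]: n=2, unbiased het = 2*(1-0.5)=... = 0.5*2/1? compute: 2/1*(1-0.5^2-0.5^2)=1.0? No:
    # n/(n-1)(1-sum p^2) = 2/1 * (1 - 0.25 - 0.25) = 1.0 -> the two callable
    # sequences differ, so the site contributes a full difference.
    m = make_matrix([[0, 1, MISSING]], positions=[50], genome_length=100)
    wins = cp.nucleotide_diversity(m, window=100, step=100)
    assert wins[0].pi == pytest.approx(1.0 / 100)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def wc_components_oracle(counts_a, counts_b):
    """Independent transcription of the haploid one-level ANOVA components."""
    counts_a, counts_b = np.asarray(counts_a, float), np.asarray(counts_b, float)
    n1, n2 = counts_a.sum(), counts_b.sum()
    nsum = n1 + n2
    nc = nsum - (n1**2 + n2**2) / nsum
    a = b = 0.0
    for al in range(len(counts_a)):
        if counts_a[al] + counts_b[al] == 0:
            continue
        p1, p2 = counts_a[al] / n1, counts_b[al] / n2
        pbar = (counts_a[al] + counts_b[al]) / nsum
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (nsum - 2)
        a += (msp - msg) / nc
        b += msg
    return a, b


def test_fst_one_on_fixed_difference():
    calls = np.array([[0] * 10 + [1] * 10])
    m = make_matrix(calls)
    pm = PopulationMap({f"s{j}": ("a" if j < 10 else "b") for j in range(20)})
    assert cp.weir_cockerham_fst(m, pm, "a", "b").fst == pytest.approx(1.0)


def test_fst_nonpositive_for_identical_frequencies():
    calls = np.array([[0] * 5 + [1] * 5 + [0] * 5 + [1] * 5])
    m = make_matrix(calls)
    pm = PopulationMap({f"s{j}": ("a" if j < 10 else "b") for j in range(20)})
    assert cp.weir_cockerham_fst(m, pm, "a", "b").fst <= 0.0


def test_fst_single_site_hand_value():
    # A: [0,0,0,1], B: [1,1,1,1] -> a = 0.5, b = 0.25, theta = 2/3 (by hand)
    m = make_matrix([[0, 0, 0, 1, 1, 1, 1, 1]])
    pm = PopulationMap({f"s{j}": ("a" if j < 4 else "b") for j in range(8)})
    res = cp.weir_cockerham_fst(m, pm, "a", "b")
    (pos, a, b) = res.per_site[0]
    assert a == pytest.approx(0.5)
    assert b == pytest.approx(0.25)
    assert res.fst == pytest.approx(2.0 / 3.0)


def test_fst_weighted_combination_matches_component_oracle():
    rng = np.random.default_rng(5)
    calls = rng.integers(0, 2, size=(3, 12))
    m = make_matrix(calls)
    pm = PopulationMap({f"s{j}": ("a" if j < 6 else "b") for j in range(12)})
    res = cp.weir_cockerham_fst(m, pm, "a", "b")
    num = den = 0.0
    for i in range(3):
        ca = np.bincount(calls[i, :6], minlength=2)
        cb = np.bincount(calls[i, 6:], minlength=2)
        if len(set(calls[i])) < 2:
            continue
        a, b = wc_components_oracle(ca, cb)
        num += a
        den += a + b
    assert res.fst == pytest.approx(num / den, abs=1e-12)


def test_fst_of_identical_groups_is_exact_negative_bias_term():
    # Two groups with identical allele frequencies and equal size n: the
    # among-group mean square vanishes, so every site gives
    # a = -MSG/n_c, b = MSG, and the weighted estimate is exactly
    # -1/(n_c - 1) with n_c = n.  (The estimator is negatively biased at
    # zero differentiation rather than clamped to zero.)
    rng = np.random.default_rng(9)
    calls = rng.integers(0, 2, size=(20, 10))
    big = np.hstack([calls, calls])  # "b" duplicates "a" sample for sample
    m2 = make_matrix(big)
    pm = PopulationMap({f"s{j}": ("a" if j < 10 else "b") for j in range(20)})
    fst = cp.weir_cockerham_fst(m2, pm, "a", "b").fst
    assert fst == pytest.approx(-1.0 / 9.0, abs=1e-12)


def test_fst_unknown_group_errors(two_group_map):
    m = make_matrix(np.tile([0, 1, 0, 1], (2, 1)))
    with pytest.raises(KeyError):
        cp.weir_cockerham_fst(m, two_group_map, "a", "nope")


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def test_tajima_constants_a1():
    c = cp.tajima_constants(4)
    assert c["a1"] == pytest.approx(1 + 0.5 + 1 / 3)


def test_tajimas_d_hand_evaluation():
    # n=4, S=3, pi_total=1.5; constants evaluated independently below
    n = 4
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    S, pi_total = 3, 1.5
    expected = (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))

    # build a 4-sample matrix with S=3 and pi_total=1.5:
    # three sites each with one singleton -> pi_total = 3 * 2*3/12? compute:
    # per site with 1 alt of 4: h = 4/3*(1-(0.75^2+0.25^2)) = 0.5; total 1.5
    calls = np.zeros((3, 4), dtype=int)
    for i in range(3):
        calls[i, i] = 1
    m = make_matrix(calls)
    res = cp.tajimas_d(m)
    assert res.S == 3
    assert res.pi_total == pytest.approx(1.5)
    assert res.D == pytest.approx(expected, abs=1e-12)
    assert res.D == pytest.approx(-0.754451, abs=1e-5)


def test_tajimas_d_undefined_without_segregating_sites():
    m = make_matrix(np.ones((2, 4), dtype=int))  # every site fixed for the alt
    with pytest.warns(UserWarning):
        res = cp.tajimas_d(m)
    assert math.isnan(res.D) and res.S == 0


def test_tajimas_d_invariant_under_sample_relabeling():
    rng = np.random.default_rng(21)
    calls = rng.integers(0, 2, size=(15, 8))
    m = make_matrix(calls)
    d1 = cp.tajimas_d(m).D
    perm = rng.permutation(8)
    d2 = cp.tajimas_d(make_matrix(calls[:, perm])).D
    assert d1 == pytest.approx(d2, abs=1e-12)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def test_pca_duplicate_samples_coincide_and_groups_separate():
    rng = np.random.default_rng(2)
    a = rng.integers(0, 2, size=20)
    b = 1 - a
    calls = np.column_stack([a, a, a, b, b, b])
    m = make_matrix(calls)
    res = cp.pca(m, k=2)
    c = res.coordinates
    assert np.allclose(c["s0"], c["s1"])
    axis1 = np.array([c[f"s{j}"][0] for j in range(6)])
    assert np.sign(axis1[:3]).tolist() != np.sign(axis1[3:]).tolist()
    assert abs(axis1[:3].mean() - axis1[3:].mean()) > 1.0
    # spectral sanity
    assert np.all(np.diff(res.explained) <= 1e-12)
    assert res.explained.sum() <= 1.0 + 1e-9


def test_pca_monomorphic_errors():
    m = make_matrix(np.ones((4, 5), dtype=int))
    with pytest.raises(ValueError):
        cp.pca(m, k=2)


def test_mds_round_trips_euclidean_embeddable_distances():
    # six samples, each with a private singleton site: all pairs are
    # equidistant (a regular simplex, exactly Euclidean-embeddable), so the
    # full-rank embedding must reproduce the Hamming distances.
    n = 6
    calls = np.eye(n, dtype=int)
    m = make_matrix(calls)
    D, names = cp.hamming_distance_matrix(m)
    res = cp.mds(m, k=n - 1)
    pts = np.array([res.coordinates[name] for name in names])
    recon = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    assert np.allclose(recon, D, atol=1e-8)


def test_mds_identical_samples_collapse():
    calls = np.zeros((5, 4), dtype=int)
    m = make_matrix(calls)
    with pytest.warns(UserWarning):
        res = cp.mds(m, k=2)
    coords = np.array(list(res.coordinates.values()))
    assert np.allclose(coords, 0.0)


def test_mds_equilateral_for_three_equidistant_samples():
    # three samples pairwise distance 2/3 over 3 sites
    calls = np.array([[0, 1, 2]] * 2 + [[0, 0, 0]])
    m = make_matrix(calls)
    res = cp.mds(m, k=2)
    pts = np.array(list(res.coordinates.values()))
    d = [np.linalg.norm(pts[i] - pts[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
    assert max(d) - min(d) < 1e-8
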