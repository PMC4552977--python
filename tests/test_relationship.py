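"""Pedigree A, genomic G, origin-aware G and the single-step H inverse."""

import numpy as np
import pytest

from rrgsim.relationship import (
    PedigreeTable,
    a_inverse,
    blend_G,
    h_inverse,
    origin_aware_G,
    pedigree_A,
    pedigree_inbreeding,
    vanraden_G,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def recursive_kinship(ped: PedigreeTable):
    """Textbook recursive coancestry (memoized), independent of the tabular
    implementation: phi(i,i) = (1 + phi(s_i, d_i))/2, phi(i,j) = mean of
    parental coancestries for the younger individual."""
    s, d = ped.parent_indices()
    cache = {}

    def phi(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        if (i, j) in cache:
            return cache[(i, j)]
        if i == j:
            v = 0.5 * (1.0 + phi(s[i], d[i]))
        else:  # j is the later-listed individual
            v = 0.5 * (phi(i, s[j]) + phi(i, d[j]))
        cache[(i, j)] = v
        return v

    n = ped.size
    A = np.array([[2.0 * phi(i, j) for j in range(n)] for i in range(n)])
    return A


def random_pedigree(n, n_founders, rng):
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    for i in range(n_founders, n):
        sire[i] = rng.integers(0, i)
        dam[i] = rng.integers(0, i)
    return PedigreeTable(np.arange(n), sire, dam)


# ---------------------------------------------------------------------------
# Pedigree A
# ---------------------------------------------------------------------------

class TestPedigreeA:
    def test_unrelated_founders_identity(self):
        ped = PedigreeTable([1, 2, 3], [-1, -1, -1], [-1, -1, -1])
        A, F = pedigree_A(ped)
        assert np.array_equal(A, np.eye(3))
        assert np.allclose(F, 0.0)

    def test_full_sibs_half_relationship(self):
        ped = PedigreeTable([0, 1, 2, 3], [-1, -1, 0, 0], [-1, -1, 1, 1])
        A, F = pedigree_A(ped)
        assert A[2, 3] == pytest.approx(0.5)
        assert np.allclose(F, 0.0)

    def test_selfing_gives_half_inbreeding(self):
        ped = PedigreeTable([0, 1], [-1, 0], [-1, 0])
        A, F = pedigree_A(ped)
        assert F[1] == pytest.approx(0.5)
        assert A[1, 1] == pytest.approx(1.5)

    def test_matches_recursive_oracle_on_random_pedigree(self, rng):
        ped = random_pedigree(50, 8, rng)
        A, F = pedigree_A(ped)
        assert np.allclose(A, recursive_kinship(ped), atol=1e-12)
        assert np.all((A >= -1e-12) & (A <= 2 + 1e-12))
        # PSD
        assert np.min(np.linalg.eigvalsh(A)) > -1e-9

    def test_inbreeding_never_decreases_along_selfing_chain(self):
        n = 6
        ped = PedigreeTable(
            np.arange(n), np.r_[-1, np.arange(n - 1)], np.r_[-1, np.arange(n - 1)]
        )
        F = pedigree_inbreeding(ped)
        assert np.all(np.diff(F) >= 0)
        # F converges to 1 - (1/2)^k
        assert F[5] == pytest.approx(1 - 0.5**5, abs=1e-12)

    def test_parent_after_offspring_rejected(self):
        with pytest.raises(ValueError):
            PedigreeTable([0, 1], [1, -1], [-1, -1])

    def test_a_inverse_matches_dense_inverse(self, rng):
        ped = random_pedigree(40, 6, rng)
        A, F = pedigree_A(ped)
        Ainv = a_inverse(ped, F).toarray()
        assert np.allclose(Ainv, np.linalg.inv(A), atol=1e-8)


# ---------------------------------------------------------------------------
# Genomic G
# ---------------------------------------------------------------------------

class TestVanRadenG:
    def test_matches_naive_double_loop(self, rng):
        D = rng.integers(0, 3, size=(5, 20)).astype(float)
        G = vanraden_G(D)
        p = D.mean(axis=0) / 2
        scale = 2 * np.sum(p * (1 - p))
        Z = D - 2 * p
        expected = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                expected[i, j] = sum(Z[i, k] * Z[j, k] for k in range(20)) / scale
        expected /= np.mean(np.diag(expected))
        assert np.allclose(G, expected)

    def test_duplicated_individual_identical_rows(self, rng):
        D = rng.integers(0, 3, size=(4, 30)).astype(float)
        D = np.vstack([D, D[0]])
        G = vanraden_G(D)
        assert np.allclose(G[0], G[4])
        assert G[0, 0] == pytest.approx(G[4, 4])

    def test_mean_diagonal_is_one(self, rng):
        D = rng.integers(0, 3, size=(8, 50)).astype(float)
        assert np.mean(np.diag(vanraden_G(D))) == pytest.approx(1.0)

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError):
            vanraden_G(np.full((4, 10), 2.0))


class TestOriginAwareG:
    def test_single_population_proportional_to_biallelic_G(self, rng):
        """Two purebred groups drawn from one genotype set, no hybrids: the
        multiallelic class coding collapses to the biallelic matrix."""
        D = rng.integers(0, 3, size=(6, 40)).astype(float)
        G_bi = vanraden_G(D)
        G_multi = origin_aware_G({"P1": D, "P2": np.empty((0, 40))})
        assert np.allclose(G_multi, G_bi, atol=1e-5)

    def test_duplicated_hybrid_identical_rows(self, rng):
        D1 = rng.integers(0, 3, size=(4, 25)).astype(float)
        D2 = rng.integers(0, 3, size=(4, 25)).astype(float)
        gam = rng.integers(0, 2, size=(3, 2, 25)).astype(np.uint8)
        gam[2] = gam[0]
        G = origin_aware_G({"A": D1, "B": D2}, gam)
        n = 8
        assert np.allclose(G[n + 0], G[n + 2], atol=1e-5)

    def test_mean_diagonal_normalized(self, rng):
        D1 = rng.integers(0, 3, size=(5, 30)).astype(float)
        D2 = rng.integers(0, 3, size=(5, 30)).astype(float)
        gam = rng.integers(0, 2, size=(4, 2, 30)).astype(np.uint8)
        G = origin_aware_G({"A": D1, "B": D2}, gam)
        assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=1e-5)
        assert np.allclose(G, G.T, atol=1e-5)


# ---------------------------------------------------------------------------
# Single-step H
# ---------------------------------------------------------------------------

def closed_form_H(A, G, idx):
    """Conditional-expectation form of H for the oracle: the ungenotyped
    block is corrected through A12 A22^-1 (G - A22) A22^-1 A21."""
    n = A.shape[0]
    mask = np.zeros(n, bool)
    mask[idx] = True
    perm = np.r_[np.flatnonzero(~mask), np.flatnonzero(mask)]
    Ap = A[np.ix_(perm, perm)]
    n1 = n - len(idx)
    A11, A12, A22 = Ap[:n1, :n1], Ap[:n1, n1:], Ap[n1:, n1:]
    A22i = np.linalg.inv(A22)
    H11 = A11 + A12 @ A22i @ (G - A22) @ A22i @ A12.T
    H12 = A12 @ A22i @ G
    Hp = np.block([[H11, H12], [H12.T, G]])
    H = np.empty_like(Hp)
    H[np.ix_(perm, perm)] = Hp
    return H


class TestHInverse:
    def test_G_equal_A22_recovers_A_inverse(self, rng):
        ped = random_pedigree(12, 4, rng)
        A, F = pedigree_A(ped)
        idx = np.array([5, 8, 11])
        A22 = A[np.ix_(idx, idx)]
        hinv = h_inverse(a_inverse(ped, F), A22, A22, idx, blend_weight=1.0)
        assert np.allclose(hinv.to_dense(), np.linalg.inv(A), atol=1e-8)

    def test_all_genotyped_recovers_blended_G_inverse(self, rng):
        ped = random_pedigree(6, 3, rng)
        A, F = pedigree_A(ped)
        D = rng.integers(0, 3, size=(6, 60)).astype(float)
        G = vanraden_G(D)
        idx = np.arange(6)
        hinv = h_inverse(a_inverse(ped, F), A, G, idx, blend_weight=0.99)
        Gb = blend_G(G, A, 0.99)
        assert np.allclose(hinv.to_dense(), np.linalg.inv(Gb), atol=1e-7)

    def test_toy_matches_closed_form_H(self, rng):
        """6-individual pedigree, 3 genotyped: inverting H^-1 recovers the
        conditional-expectation form of H."""
        ped = PedigreeTable(
            np.arange(6), [-1, -1, 0, 0, 2, 2], [-1, -1, 1, 1, 3, 3]
        )
        A, F = pedigree_A(ped)
        idx = np.array([3, 4, 5])
        D = rng.integers(0, 3, size=(3, 80)).astype(float)
        G = blend_G(vanraden_G(D), A[np.ix_(idx, idx)], 0.95)
        hinv = h_inverse(a_inverse(ped, F), A[np.ix_(idx, idx)], G, idx,
                         blend_weight=1.0)
        H = np.linalg.inv(hinv.to_dense())
        assert np.allclose(H, closed_form_H(A, G, idx), atol=1e-7)

    def test_matvec_and_diagonal_consistent_with_dense(self, rng):
        ped = random_pedigree(15, 5, rng)
        A, F = pedigree_A(ped)
        idx = np.array([9, 10, 14])
        D = rng.integers(0, 3, size=(3, 50)).astype(float)
        G = vanraden_G(D)
        hinv = h_inverse(a_inverse(ped, F), A[np.ix_(idx, idx)], G, idx)
        M = hinv.to_dense()
        x = rng.normal(size=15)
        assert np.allclose(hinv.matvec(x), M @ x)
        assert np.allclose(hinv.diagonal(), np.diag(M))

    def test_singular_G_without_blending_rejected(self, rng):
        ped = random_pedigree(5, 2, rng)
        A, F = pedigree_A(ped)
        idx = np.array([3, 4])
        G = np.ones((2, 2))  # singular
        with pytest.raises(ValueError, match="blend"):
            h_inverse(a_inverse(ped, F), A[np.ix_(idx, idx)], G, idx,
                      blend_weight=1.0)
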