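"""Pedigree and genomic relationship matrices.

Implements the numerator relationship matrix A by the tabular method, its
sparse inverse by Henderson's rules (with inbreeding), VanRaden's genomic
matrix G from observed allele frequencies, an origin-aware multiallelic G
for interpopulation hybrids, and the single-step combined inverse
H^-1 = A_all^-1 + [0 0; 0 G^-1 - A22^-1] on the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "PedigreeTable",
    "pedigree_A",
    "pedigree_inbreeding",
    "a_inverse",
    "vanraden_G",
    "origin_aware_G",
    "blend_G",
    "HInverse",
    "h_inverse",
]


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class PedigreeTable:
    """Ordered pedigree records: parents precede offspring, -1 = unknown.

    ``ids`` are arbitrary global labels; ``sire``/``dam`` refer to earlier
    ids (or -1).  Internally positions 0..n-1 follow the given order.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not (self.ids.size == self.sire.size == self.dam.size):
            raise ValueError("pedigree columns must align")
        if np.unique(self.ids).size != self.ids.size:
            raise ValueError("duplicate ids in pedigree")
        pos = {int(i): k for k, i in enumerate(self.ids)}
        self._pos = pos
        self._sire_idx = np.empty(self.ids.size, dtype=np.int64)
        self._dam_idx = np.empty(self.ids.size, dtype=np.int64)
        for k in range(self.ids.size):
            for src, dst in ((self.sire, self._sire_idx), (self.dam, self._dam_idx)):
                p = int(src[k])
                if p == -1:
                    dst[k] = -1
                else:
                    if p not in pos or pos[p] >= k:
                        raise ValueError(
                            f"parent {p} of {int(self.ids[k])} not listed earlier"
                        )
                    dst[k] = pos[p]

    @property
    def size(self) -> int:
        return int(self.ids.size)

    def positions(self, ids: np.ndarray) -> np.ndarray:
        return np.array([self._pos[int(i)] for i in np.asarray(ids)], dtype=np.int64)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return self._sire_idx, self._dam_idx


def pedigree_A(ped: PedigreeTable) -> tuple[np.ndarray, np.ndarray]:
    """Tabular-method numerator relationship matrix and inbreeding vector.

    Returns (A, F) with F = diag(A) - 1.  Memory is O(n^2); intended for
    pedigrees up to a few thousand individuals.
    """
    n = ped.size
    s, d = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
            row = 0.5 * (A[si, :i] + A[di, :i])
        elif si >= 0:
            A[i, i] = 1.0
            row = 0.5 * A[si, :i]
        elif di >= 0:
            A[i, i] = 1.0
            row = 0.5 * A[di, :i]
        else:
            A[i, i] = 1.0
            row = np.zeros(i)
        A[i, :i] = row
        A[:i, i] = row
    return A, np.diag(A) - 1.0


def pedigree_inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients via the tabular method (memory-lean variant
    would be Meuwissen-Luo; tabular is adequate at this package's scales)."""
    return pedigree_A(ped)[1]


def a_inverse(ped: PedigreeTable, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules, accounting for parental inbreeding.

    Mendelian sampling variance d_i = 0.5 - 0.25 (F_s + F_d), with F = 0 for
    unknown parents and 0.75 (resp. 1) when one (resp. both) parent unknown.
    """
    n = ped.size
    s, d = ped.parent_indices()
    if F is None:
        F = pedigree_inbreeding(ped)
    rows, cols, vals = [], [], []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        si, di = s[i], d[i]
        fs = F[si] if si >= 0 else 0.0
        fd = F[di] if di >= 0 else 0.0
        if si >= 0 and di >= 0:
            dii = 0.5 - 0.25 * (fs + fd)
        elif si >= 0 or di >= 0:
            dii = 0.75 - 0.25 * (fs + fd)
        else:
            dii = 1.0
        w = 1.0 / dii
        add(i, i, w)
        for p in (si, di):
            if p >= 0:
                add(i, p, -0.5 * w)
                add(p, i, -0.5 * w)
        for p in (si, di):
            for q in (si, di):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * w)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------------
# Genomic relationship matrices
# ---------------------------------------------------------------------------

def vanraden_G(
    dosages: np.ndarray, allele_freqs: np.ndarray | None = None
) -> np.ndarray:
    """VanRaden genomic relationship matrix from 0/1/2 dosages.

    Centers by observed allele frequencies (computed from ``dosages`` when
    not given), scales by 2 sum p(1-p) and normalizes to mean diagonal 1.
    """
    D = np.asarray(dosages, dtype=float)
    if D.ndim != 2:
        raise ValueError("dosages must be individuals x loci")
    p = D.mean(axis=0) / 2.0 if allele_freqs is None else np.asarray(allele_freqs, float)
    scale = 2.0 * np.sum(p * (1.0 - p))
    if scale <= 0:
        raise ValueError("no polymorphic loci: G scale is zero")
    Z = D - 2.0 * p
    G = (Z @ Z.T) / scale
    G /= np.mean(np.diag(G))
    return G


def origin_aware_G(
    parent_dosages: dict[str, np.ndarray],
    hybrid_gametotypes: np.ndarray | None = None,
) -> np.ndarray:
    """Multiallelic G distinguishing the population of origin of alleles.

    Every biallelic marker is recoded as four allele classes (0 and 1 from
    each of the two parental populations).  A purebred individual carries two
    copies of its own-origin classes; a hybrid carries one allele of each
    origin, taken from its gametotype (ordered pair: allele from population 1
    parent, allele from population 2 parent).

    Parameters
    ----------
    parent_dosages
        Mapping of exactly two population labels to (n_pop, m) dosage
        matrices, in the order matching the gametotype columns.
    hybrid_gametotypes
        (n_hyb, 2, m) array of hybrid alleles with known origin, or None.

    Returns the centered class-dosage cross-product scaled by
    sum over classes of p(1-p), normalized to mean diagonal 1.  Row order:
    population 1 parents, population 2 parents, hybrids.
    """
    if len(parent_dosages) != 2:
        raise ValueError("exactly two parental populations are required")
    (lab1, D1), (lab2, D2) = parent_dosages.items()
    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    m = D1.shape[1]
    if D2.shape[1] != m:
        raise ValueError("populations must share loci")
    n1, n2 = D1.shape[0], D2.shape[0]
    if hybrid_gametotypes is None:
        H = np.empty((0, 2, m), dtype=np.uint8)
    else:
        H = np.asarray(hybrid_gametotypes)
        if H.ndim != 3 or H.shape[1] != 2 or H.shape[2] != m:
            raise ValueError("gametotypes must have shape (n, 2, m)")
    nh = H.shape[0]
    n = n1 + n2 + nh
    # Class dosages, classes ordered (1_pop1, 0_pop1, 1_pop2, 0_pop2).
    C = np.zeros((n, 4 * m), dtype=np.float32)
    C[:n1, 0::4] = D1
    C[:n1, 1::4] = 2.0 - D1
    C[n1 : n1 + n2, 2::4] = D2
    C[n1 : n1 + n2, 3::4] = 2.0 - D2
    if nh:
        h1 = H[:, 0, :].astype(np.float32)
        h2 = H[:, 1, :].astype(np.float32)
        C[n1 + n2 :, 0::4] = h1
        C[n1 + n2 :, 1::4] = 1.0 - h1
        C[n1 + n2 :, 2::4] = h2
        C[n1 + n2 :, 3::4] = 1.0 - h2
    p = C.mean(axis=0) / 2.0
    scale = float(np.sum(p * (1.0 - p)))
    if scale <= 0:
        raise ValueError("no polymorphic allele classes")
    C -= 2.0 * p
    G = (C @ C.T).astype(float) / scale
    G /= np.mean(np.diag(G))
    return G


def blend_G(G: np.ndarray, A22: np.ndarray, weight: float = 0.99) -> np.ndarray:
    """Blend G with its pedigree counterpart to guarantee invertibility."""
    return weight * G + (1.0 - weight) * A22


# ---------------------------------------------------------------------------
# Single-step H inverse
# ---------------------------------------------------------------------------

@dataclass
class HInverse:
    """H^-1 held as sparse A_all^-1 plus a dense correction on the genotyped
    block; supports matrix-vector products without densifying."""

    a_inv: sp.csr_matrix
    correction: np.ndarray  # G^-1 - A22^-1 (dense, genotyped block)
    genotyped: np.ndarray  # positions of genotyped individuals in A_all order

    @property
    def n(self) -> int:
        return self.a_inv.shape[0]

    def matvec(self, x: np.ndarray) -> np.ndarray:
        y = self.a_inv @ x
        y[self.genotyped] += self.correction @ x[self.genotyped]
        return y

    def diagonal(self) -> np.ndarray:
        d = np.asarray(self.a_inv.diagonal()).copy()
        d[self.genotyped] += np.diag(self.correction)
        return d

    def to_dense(self) -> np.ndarray:
        M = self.a_inv.toarray()
        ix = np.ix_(self.genotyped, self.genotyped)
        M[ix] += self.correction
        return M


def h_inverse(
    a_all_inv: sp.spmatrix | np.ndarray,
    A22: np.ndarray,
    G: np.ndarray,
    genotyped_index: np.ndarray,
    blend_weight: float = 0.99,
) -> HInverse:
    """Single-step H^-1 = A_all^-1 + [0 0; 0 G*^-1 - A22^-1].

    ``G`` is blended as G* = w G + (1-w) A22 before inversion (w =
    ``blend_weight``); pass ``blend_weight=1`` to use G as is, which fails
    with a clear message when G is singular.
    """
    a_all_inv = sp.csr_matrix(a_all_inv)
    A22 = np.asarray(A22, dtype=float)
    G = np.asarray(G, dtype=float)
    idx = np.asarray(genotyped_index, dtype=np.int64)
    if A22.shape != G.shape or A22.shape[0] != idx.size:
        raise ValueError("A22, G and genotyped_index must agree in size")
    Gb = blend_G(G, A22, blend_weight) if blend_weight < 1.0 else G
    try:
        G_inv = np.linalg.inv(Gb)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "G is singular; enable blending (blend_weight < 1)"
        ) from err
    A22_inv = np.linalg.inv(A22)
    return HInverse(a_all_inv, G_inv - A22_inv, idx)
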