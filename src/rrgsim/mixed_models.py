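"""Bivariate linear mixed models for hybrid progeny-test analysis.

Two model families are provided, mirroring how reciprocal recurrent
selection data are analysed:

* a two-kernel general-combining-ability (GCA) model, where each hybrid
  record carries one additive effect from each parental population and the
  kernels are 0.5*A (pedigree) or a population-specific G (genomic);
* a single-kernel individual model, where every individual (parents and
  hybrids) has its own breeding value and the kernel is the combined
  single-step matrix H (supplied through its inverse).

Both are bivariate in bunch weight (BW) and bunch number (BN) with a
Kronecker covariance term_covariance (x) kernel, per-trait overall means as
the only fixed effects, and independent residuals across traits.  Systems
are solved exactly (dense) when small and by preconditioned conjugate
gradients on a matrix-free operator when large.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from .relationship import HInverse

__all__ = [
    "VarComps",
    "BLUPSolution",
    "solve_gca_bivariate",
    "solve_ssgblup_bivariate",
    "estimate_varcomps_em",
    "predict_cross_value",
]

_PSD_TOL = 1e-10


@dataclass
class VarComps:
    """Variance components: per random term a 2x2 (BW, BN) covariance
    matrix, plus per-trait residual variances (residual covariance = 0)."""

    terms: dict[str, np.ndarray]
    resid: np.ndarray  # (2,) residual variances, (BW, BN)

    def __post_init__(self) -> None:
        self.resid = np.asarray(self.resid, dtype=float)
        if self.resid.shape != (2,) or np.any(self.resid <= 0):
            raise ValueError("residual variances must be two positive values")
        for name, S in self.terms.items():
            S = np.asarray(S, dtype=float)
            if S.shape != (2, 2) or abs(S[0, 1] - S[1, 0]) > 1e-8:
                raise ValueError(f"term {name}: covariance must be symmetric 2x2")
            if np.min(np.linalg.eigvalsh(S)) < -1e-8 * max(1.0, np.trace(S)):
                raise ValueError(f"term {name}: covariance not PSD")
            self.terms[name] = S


@dataclass
class BLUPSolution:
    """Fitted means, random-effect solutions and solver diagnostics."""

    means: np.ndarray  # (2,) per-trait fitted means
    effects: dict[str, np.ndarray]  # term -> (q, 2) solutions
    converged: bool = True
    n_iter: int = 0
    residual_norm: float = 0.0
    extra: dict = field(default_factory=dict)


def _term_precision(S: np.ndarray) -> np.ndarray | None:
    """Inverse of a 2x2 term covariance; None flags a null (dropped) term."""
    S = np.asarray(S, dtype=float)
    if np.trace(S) < _PSD_TOL:
        return None
    return np.linalg.inv(S)


# ---------------------------------------------------------------------------
# Two-kernel GCA model (dense)
# ---------------------------------------------------------------------------

def solve_gca_bivariate(
    y: np.ndarray,
    parent1_index: np.ndarray,
    parent2_index: np.ndarray,
    K1: np.ndarray,
    K2: np.ndarray,
    varcomps: VarComps,
    term_names: tuple[str, str] = ("pop1", "pop2"),
) -> BLUPSolution:
    """Bivariate GCA model: y_t = mu_t + u1_t[parent1] + u2_t[parent2] + e_t.

    ``K1``/``K2`` are the covariance kernels of the two parental GCA vectors
    (0.5*A or a genomic G); ``varcomps.terms`` must carry 2x2 covariance
    matrices under ``term_names``.  Solved exactly via the dense mixed-model
    equations; suitable for up to a few hundred parents per population.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if y.shape != (n, 2):
        raise ValueError("y must be (n, 2)")
    i1 = np.asarray(parent1_index, dtype=np.int64)
    i2 = np.asarray(parent2_index, dtype=np.int64)
    K1 = np.asarray(K1, dtype=float)
    K2 = np.asarray(K2, dtype=float)
    p1, p2 = K1.shape[0], K2.shape[0]
    if i1.max(initial=-1) >= p1 or i2.max(initial=-1) >= p2:
        raise ValueError("record links exceed kernel size")

    L1 = _term_precision(varcomps.terms[term_names[0]])
    L2 = _term_precision(varcomps.terms[term_names[1]])
    if L1 is None or L2 is None:
        # Null additive covariance: GCA shrink to zero, means = trait means.
        return BLUPSolution(
            means=y.mean(axis=0),
            effects={term_names[0]: np.zeros((p1, 2)),
                     term_names[1]: np.zeros((p2, 2))},
        )
    K1_inv = np.linalg.inv(K1)
    K2_inv = np.linalg.inv(K2)

    # Per-trait incidence cross-products (identical across traits).
    one = np.ones(n)
    Z1t_1 = np.bincount(i1, minlength=p1).astype(float)
    Z2t_1 = np.bincount(i2, minlength=p2).astype(float)
    Z1tZ1 = np.zeros((p1, p1))
    np.add.at(Z1tZ1, (i1, i1), 1.0)
    Z2tZ2 = np.zeros((p2, p2))
    np.add.at(Z2tZ2, (i2, i2), 1.0)
    Z1tZ2 = np.zeros((p1, p2))
    np.add.at(Z1tZ2, (i1, i2), 1.0)

    q = 1 + p1 + p2  # unknowns per trait
    W = np.zeros((q, q))
    W[0, 0] = n
    W[0, 1 : 1 + p1] = Z1t_1
    W[1 : 1 + p1, 0] = Z1t_1
    W[0, 1 + p1 :] = Z2t_1
    W[1 + p1 :, 0] = Z2t_1
    W[1 : 1 + p1, 1 : 1 + p1] = Z1tZ1
    W[1 + p1 :, 1 + p1 :] = Z2tZ2
    W[1 : 1 + p1, 1 + p1 :] = Z1tZ2
    W[1 + p1 :, 1 : 1 + p1] = Z1tZ2.T

    C = np.zeros((2 * q, 2 * q))
    rhs = np.zeros(2 * q)
    for t in range(2):
        sl = slice(t * q, (t + 1) * q)
        C[sl, sl] += W / varcomps.resid[t]
        r = np.zeros(q)
        r[0] = y[:, t].sum()
        r[1 : 1 + p1] = np.bincount(i1, weights=y[:, t], minlength=p1)
        r[1 + p1 :] = np.bincount(i2, weights=y[:, t], minlength=p2)
        rhs[sl] = r / varcomps.resid[t]
    for t in range(2):
        for s_ in range(2):
            blk = np.zeros((q, q))
            blk[1 : 1 + p1, 1 : 1 + p1] = L1[t, s_] * K1_inv
            blk[1 + p1 :, 1 + p1 :] = L2[t, s_] * K2_inv
            C[t * q : (t + 1) * q, s_ * q : (s_ + 1) * q] += blk

    sol = np.linalg.solve(C, rhs)
    res = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-30))
    means = np.array([sol[0], sol[q]])
    u1 = np.stack([sol[1 : 1 + p1], sol[q + 1 : q + 1 + p1]], axis=1)
    u2 = np.stack([sol[1 + p1 : q], sol[q + 1 + p1 :]], axis=1)
    return BLUPSolution(
        means=means,
        effects={term_names[0]: u1, term_names[1]: u2},
        residual_norm=res,
    )


# ---------------------------------------------------------------------------
# Single-kernel individual model (single-step)
# ---------------------------------------------------------------------------

def _as_kernel_inv(kernel_inv) -> tuple:
    """Normalize the kernel inverse to (matvec, diagonal, n)."""
    if isinstance(kernel_inv, HInverse):
        return kernel_inv.matvec, kernel_inv.diagonal(), kernel_inv.n
    M = np.asarray(kernel_inv, dtype=float)
    return (lambda x: M @ x), np.diag(M).copy(), M.shape[0]


def solve_ssgblup_bivariate(
    y: np.ndarray,
    record_index: np.ndarray,
    kernel_inv,
    varcomps: VarComps,
    term_name: str = "additive",
    cg_tol: float = 1e-8,
    max_iter: int = 20000,
    dense_threshold: int = 2000,
) -> BLUPSolution:
    """Bivariate individual model: y_t = mu_t + a_t[record_index] + e_t.

    ``kernel_inv`` is the inverse covariance kernel over all individuals —
    typically an :class:`~rrgsim.relationship.HInverse`, or a dense array for
    small systems/tests.  Every individual in the kernel receives a breeding
    value for both traits, including those without records.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    idx = np.asarray(record_index, dtype=np.int64)
    matvec, kdiag, N = _as_kernel_inv(kernel_inv)
    if idx.size != n or idx.max(initial=-1) >= N:
        raise ValueError("record_index inconsistent with kernel size")

    Lam = _term_precision(varcomps.terms[term_name])
    if Lam is None:
        return BLUPSolution(means=y.mean(axis=0), effects={term_name: np.zeros((N, 2))})

    rinv = 1.0 / varcomps.resid
    counts = np.bincount(idx, minlength=N).astype(float)
    q = 1 + N

    def apply_C(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros(x.shape, dtype=float)
        a = [x[t * q + 1 : (t + 1) * q] for t in range(2)]
        for t in range(2):
            mu = x[t * q]
            fitted = mu + a[t][idx]
            out[t * q] += rinv[t] * fitted.sum()
            out[t * q + 1 : (t + 1) * q] += rinv[t] * (
                np.bincount(idx, weights=fitted, minlength=N)
            )
        Ka = [matvec(a[t]) for t in range(2)]
        for t in range(2):
            out[t * q + 1 : (t + 1) * q] += Lam[t, 0] * Ka[0] + Lam[t, 1] * Ka[1]
        return out

    rhs = np.zeros(2 * q)
    for t in range(2):
        rhs[t * q] = rinv[t] * y[:, t].sum()
        rhs[t * q + 1 : (t + 1) * q] = rinv[t] * np.bincount(
            idx, weights=y[:, t], minlength=N
        )

    if 2 * q <= dense_threshold:
        C = np.zeros((2 * q, 2 * q))
        eye = np.eye(2 * q)
        for j in range(2 * q):
            C[:, j] = apply_C(eye[:, j])
        sol = np.linalg.solve(C, rhs)
        n_iter, converged = 0, True
    else:
        diag = np.zeros(2 * q)
        for t in range(2):
            diag[t * q] = rinv[t] * n
            diag[t * q + 1 : (t + 1) * q] = rinv[t] * counts + Lam[t, t] * kdiag
        M = spla.LinearOperator((2 * q, 2 * q), matvec=lambda x: x / diag)
        A = spla.LinearOperator((2 * q, 2 * q), matvec=apply_C)
        sol, info = spla.cg(A, rhs, rtol=cg_tol, maxiter=max_iter, M=M)
        converged = info == 0
        n_iter = info if info > 0 else max_iter if info < 0 else 0

    res = float(
        np.linalg.norm(apply_C(sol) - rhs) / max(np.linalg.norm(rhs), 1e-30)
    )
    means = np.array([sol[0], sol[q]])
    a = np.stack([sol[1:q], sol[q + 1 :]], axis=1)
    return BLUPSolution(
        means=means, effects={term_name: a},
        converged=converged, n_iter=n_iter, residual_norm=res,
    )


# ---------------------------------------------------------------------------
# EM-REML (optional path, dense, toy scale)
# ---------------------------------------------------------------------------

def estimate_varcomps_em(
    y: np.ndarray,
    term_incidence: dict[str, np.ndarray],
    term_kernels: dict[str, np.ndarray],
    start: VarComps,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[VarComps, bool, int]:
    """EM-REML for the bivariate model y_t = mu_t + sum_k Z_k u_kt + e_t.

    Dense implementation intended for small systems (a few hundred
    equations).  Returns (estimates, converged, n_iter); on non-convergence
    the best current estimates are returned with ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    names = list(term_incidence)
    Zs = [np.asarray(term_incidence[k], dtype=float) for k in names]
    Ks = [np.asarray(term_kernels[k], dtype=float) for k in names]
    K_invs = [np.linalg.inv(K) for K in Ks]
    qs = [Z.shape[1] for Z in Zs]
    W = np.concatenate([np.ones((n, 1))] + Zs, axis=1)  # per-trait design
    p = W.shape[1]
    WtW = W.T @ W
    Wty = W.T @ y  # (p, 2)

    terms = {k: np.array(start.terms[k], dtype=float) for k in names}
    resid = np.array(start.resid, dtype=float)
    converged = False
    it = 0
    offs = np.cumsum([1] + qs)  # start offsets of each term within a trait block
    for it in range(1, max_iter + 1):
        C = np.zeros((2 * p, 2 * p))
        rhs = np.zeros(2 * p)
        for t in range(2):
            sl = slice(t * p, (t + 1) * p)
            C[sl, sl] += WtW / resid[t]
            rhs[sl] = Wty[:, t] / resid[t]
        for k, Ki in enumerate(K_invs):
            Lam = _term_precision(terms[names[k]])
            if Lam is None:
                Lam = np.linalg.inv(terms[names[k]] + 1e-8 * np.eye(2))
            a, b = offs[k], offs[k] + qs[k]
            for t in range(2):
                for s_ in range(2):
                    C[t * p + a : t * p + b, s_ * p + a : s_ * p + b] += Lam[t, s_] * Ki
        C_inv = np.linalg.inv(C)
        sol = C_inv @ rhs

        new_terms = {}
        for k, Ki in enumerate(K_invs):
            a, b = offs[k], offs[k] + qs[k]
            S = np.zeros((2, 2))
            for t in range(2):
                for s_ in range(2):
                    ut = sol[t * p + a : t * p + b]
                    us = sol[s_ * p + a : s_ * p + b]
                    Cblk = C_inv[t * p + a : t * p + b, s_ * p + a : s_ * p + b]
                    S[t, s_] = (ut @ Ki @ us + np.trace(Ki @ Cblk)) / qs[k]
            new_terms[names[k]] = 0.5 * (S + S.T)
        new_resid = np.empty(2)
        for t in range(2):
            theta = sol[t * p : (t + 1) * p]
            new_resid[t] = (y[:, t] @ y[:, t] - theta @ Wty[:, t]) / (n - 1)

        delta = abs(new_resid - resid).max()
        for k in names:
            delta = max(delta, np.abs(new_terms[k] - terms[k]).max())
        terms, resid = new_terms, new_resid
        if delta < tol:
            converged = True
            break
    return VarComps(terms=terms, resid=resid), converged, it


# ---------------------------------------------------------------------------
# Cross value
# ---------------------------------------------------------------------------

def predict_cross_value(
    gca1: np.ndarray, gca2: np.ndarray, means: np.ndarray
) -> np.ndarray:
    """Expected hybrid bunch production of crosses.

    Predicted hybrid trait = mean + GCA(parent 1) + GCA(parent 2) per trait;
    production is the BW x BN product.  Accepts (2,) vectors or (n, 2)
    arrays (broadcast pairwise by row).
    """
    g1 = np.atleast_2d(np.asarray(gca1, dtype=float))
    g2 = np.atleast_2d(np.asarray(gca2, dtype=float))
    means = np.asarray(means, dtype=float)
    bw = means[0] + g1[:, 0] + g2[:, 0]
    bn = means[1] + g1[:, 1] + g2[:, 1]
    out = bw * bn
    return out if out.size > 1 else float(out[0])
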