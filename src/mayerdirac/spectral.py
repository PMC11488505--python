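"""Mayer Laplacians, Mayer Dirac operators, and their factorization.

For a Mayer N-chain with q-step boundary matrices B_{n,q}, the q-th Mayer
Laplacian at grade n is the Hermitian positive-semidefinite matrix

    L_{n,q} = B_{n+N-q,N-q} B_{n+N-q,N-q}^H  +  B_{n,q}^H B_{n,q}

whose kernel dimension equals the Mayer Betti number beta_{n,q}.  Fixing
1 <= q <= N-1 and 0 <= i < N-q, the alternating sequence of q-step and
(N-q)-step boundaries starting at grade i forms an ordinary 2-chain
complex Omega_{*,i,q}; its k-th Dirac operator D_{k,i,q} is the Hermitian
block-tridiagonal matrix whose square is block diagonal in Mayer
Laplacians.  X_{k,q} realizes the factorization Delta_q = X_{N-q} X_q.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .chain_complex import NChain, Simplex, q_step_boundary
from .tolerances import DEFAULT_TOL, TolerancePolicy

__all__ = [
    "LaplacianPair",
    "OmegaSequence",
    "DiracOperator",
    "FactorOperator",
    "SpectrumResult",
    "mayer_laplacian",
    "laplacian_entrywise",
    "omega_sequence",
    "dirac_matrix",
    "x_factor",
    "spectrum",
    "singular_values",
]


@dataclass(frozen=True)
class LaplacianPair:
    n: int
    q: int
    up: np.ndarray
    down: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.up + self.down


def mayer_laplacian(chain: NChain, n: int, q: int) -> LaplacianPair:
    """Assemble L_{n,q}; missing grades contribute zero blocks."""
    N = chain.N
    if not 1 <= q <= N - 1:
        raise ValueError(f"q must satisfy 1 <= q <= N-1 = {N - 1}, got {q}")
    Bup = q_step_boundary(chain, n + N - q, N - q).matrix
    Bdown = q_step_boundary(chain, n, q).matrix
    up = Bup @ Bup.conj().T
    down = Bdown.conj().T @ Bdown
    return LaplacianPair(n=n, q=q, up=up, down=down)


def laplacian_entrywise(chain: NChain, n: int, q: int) -> LaplacianPair:
    """Closed-form entrywise assembly of L_{n,q} (simplicial chains only).

    Down entries sum ``w_delta^2 |alpha_q|^2 / (w_sigma w_tau) xi^{[j]-[s]}``
    over common q-fold faces delta of the pair; Up entries sum the analogous
    coface expression with weight factor ``w_tau w_sigma / w_delta^2``.  In
    the full tuple complex the removal index is not unique, so the formula
    is restricted to simplicial chains.
    """
    N = chain.N
    if not 1 <= q <= N - 1:
        raise ValueError(f"q out of range [1, {N - 1}]: {q}")
    basis_n = chain.basis(n)
    if not all(isinstance(s, Simplex) for s in basis_n):
        raise TypeError("entrywise Laplacian requires a simplicial chain")
    dim_n = len(basis_n)
    alpha_q = chain.context.alpha[q]
    alpha_Nq = chain.context.alpha[N - q]
    down = np.zeros((dim_n, dim_n), dtype=complex)
    if n >= q:
        for a, tau in enumerate(basis_n):
            for b, sigma in enumerate(basis_n):
                acc = 0.0 + 0.0j
                for j in combinations(range(n + 1), q):
                    delta = sigma.face(j)
                    for s in combinations(range(n + 1), q):
                        if tau.face(s) == delta:
                            acc += (
                                chain.weight(delta) ** 2
                                * abs(alpha_q) ** 2
                                / (chain.weight(sigma) * chain.weight(tau))
                                * chain.context.xi_pow(sum(j) - sum(s))
                            )
                down[a, b] = acc
    up = np.zeros((dim_n, dim_n), dtype=complex)
    for delta in chain.basis(n + N - q):
        m = len(delta.vertices)
        for j in combinations(range(m), N - q):
            tau = delta.face(j)
            for s in combinations(range(m), N - q):
                sigma = delta.face(s)
                a, b = chain.index(n, tau), chain.index(n, sigma)
                up[a, b] += (
                    chain.weight(tau)
                    * chain.weight(sigma)
                    * abs(alpha_Nq) ** 2
                    / chain.weight(delta) ** 2
                    * chain.context.xi_pow(sum(j) - sum(s))
                )
    return LaplacianPair(n=n, q=q, up=up, down=down)


# ---------------------------------------------------------------------------
# Omega sequences and Dirac operators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OmegaSequence:
    """The 2-chain complex of alternating q- and (N-q)-step boundaries.

    Grade j holds C_{t_j} with ``t_j = i + (j-1)/2 N + q`` for odd j and
    ``t_j = i + j/2 N`` for even j; the map T_j out of grade j is the
    q-step boundary for odd j, the (N-q)-step boundary for even positive j,
    and 0 for j = 0.
    """

    i: int
    q: int
    grade_index: tuple[int, ...]  # t_j for j = 0 .. length-1
    maps: tuple[np.ndarray, ...]  # T_j for j = 1 .. length-1
    sizes: tuple[int, ...]  # dim Omega_j

    @property
    def length(self) -> int:
        return len(self.grade_index)


def _t_index(i: int, q: int, N: int, j: int) -> int:
    return i + ((j - 1) // 2) * N + q if j % 2 else i + (j // 2) * N


def omega_sequence(chain: NChain, i: int, q: int, length: int) -> OmegaSequence:
    """Grades 0 .. length-1 of Omega_{*,i,q} with their boundary matrices."""
    N = chain.N
    if not 1 <= q <= N - 1:
        raise ValueError(f"q out of range [1, {N - 1}]: {q}")
    if not 0 <= i < N - q:
        raise ValueError(f"i must satisfy 0 <= i < N-q = {N - q}, got {i}")
    grades = tuple(_t_index(i, q, N, j) for j in range(length))
    maps = tuple(
        q_step_boundary(chain, grades[j], q if j % 2 else N - q).matrix
        for j in range(1, length)
    )
    sizes = tuple(chain.dim(t) for t in grades)
    return OmegaSequence(i=i, q=q, grade_index=grades, maps=maps, sizes=sizes)


@dataclass(frozen=True)
class DiracOperator:
    k: int
    i: int
    q: int
    matrix: np.ndarray
    block_sizes: tuple[int, ...]

    def block_slices(self) -> list[slice]:
        offsets = np.concatenate([[0], np.cumsum(self.block_sizes)])
        return [slice(int(a), int(b)) for a, b in zip(offsets[:-1], offsets[1:])]


def dirac_matrix(chain: NChain, k: int, i: int, q: int) -> DiracOperator:
    """Hermitian block-tridiagonal Mayer Dirac D_{k,i,q} on Omega_0..Omega_{k+1}."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    omega = omega_sequence(chain, i, q, k + 2)
    sizes = omega.sizes
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    total = int(offsets[-1])
    D = np.zeros((total, total), dtype=complex)
    for j in range(1, k + 2):
        T = omega.maps[j - 1]  # maps Omega_j -> Omega_{j-1}
        r = slice(int(offsets[j - 1]), int(offsets[j]))
        c = slice(int(offsets[j]), int(offsets[j + 1]))
        D[r, c] = T
        D[c, r] = T.conj().T
    return DiracOperator(k=k, i=i, q=q, matrix=D, block_sizes=tuple(int(s) for s in sizes))


@dataclass(frozen=True)
class FactorOperator:
    k: int
    q: int
    matrix: np.ndarray
    block_sizes: tuple[int, ...]


def x_factor(chain: NChain, k: int, q: int, n_top: int | None = None) -> FactorOperator:
    """The factor operator X_{k,q} on grades 0 .. n_top (default k+N-q).

    Block (i, j) is B_{j,q} when j = i + q, the adjoint of B_{i,N-q} when
    i = j + N - q, and zero otherwise.  The adjoint of X_{k,q} is the X
    operator with parameter N-q truncated to the *same* grade range, i.e.
    ``x_factor(chain, k + N - 2q, N - q)`` whenever that k-index is
    non-negative (equivalently ``x_factor(chain, 0, N - q, n_top=k+N-q)``
    zero-padded; the two spans coincide only when q = N/2).  The product
    of the adjoint pair is block diagonal: Mayer Laplacian totals
    L_{0,q}..L_{k,q} followed by Down blocks up to grade k+N-q.
    """
    N = chain.N
    if not 1 <= q <= N - 1:
        raise ValueError(f"q out of range [1, {N - 1}]: {q}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    nblk = (k + N - q if n_top is None else n_top) + 1
    sizes = tuple(chain.dim(m) for m in range(nblk))
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    total = int(offsets[-1])
    X = np.zeros((total, total), dtype=complex)
    for bi in range(nblk):
        r = slice(int(offsets[bi]), int(offsets[bi + 1]))
        for bj in range(nblk):
            c = slice(int(offsets[bj]), int(offsets[bj + 1]))
            if bj == bi + q:
                X[r, c] = q_step_boundary(chain, bj, q).matrix
            elif bi == bj + N - q:
                X[r, c] = q_step_boundary(chain, bi, N - q).matrix.conj().T
    return FactorOperator(k=k, q=q, matrix=X, block_sizes=sizes)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumResult:
    eigenvalues: np.ndarray  # ascending, real
    nullity: int
    threshold: float

    @property
    def positive(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues > self.threshold]

    @property
    def negative(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < -self.threshold]


def spectrum(
    matrix: np.ndarray,
    tol: TolerancePolicy = DEFAULT_TOL,
    hermitian_tol: float = 1e-10,
) -> SpectrumResult:
    """Eigenvalues of a Hermitian matrix with the shared nullity threshold.

    Non-Hermitian inputs (beyond symmetrization tolerance) are a contract
    error: the X factor operators must go through :func:`singular_values`.
    """
    M = np.asarray(matrix, dtype=complex)
    if M.size == 0:
        return SpectrumResult(np.zeros(0), 0, tol.floor)
    dev = float(np.max(np.abs(M - M.conj().T)))
    if dev > hermitian_tol:
        raise ValueError(
            f"matrix is not Hermitian (max deviation {dev:.2e}); "
            "use singular_values for non-Hermitian operators"
        )
    H = (M + M.conj().T) / 2
    eigs = np.linalg.eigvalsh(H)
    lam_max = float(np.max(np.abs(eigs))) if eigs.size else 0.0
    thr = tol.null_threshold(M.shape[0], lam_max)
    nullity = int(np.sum(np.abs(eigs) <= thr))
    return SpectrumResult(eigenvalues=eigs, nullity=nullity, threshold=thr)


def singular_values(matrix: np.ndarray) -> np.ndarray:
    """Descending singular values (the spectral route for X operators)."""
    M = np.asarray(matrix, dtype=complex)
    if M.size == 0:
        return np.zeros(0)
    return np.linalg.svd(M, compute_uv=False)
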