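"""Mayer homology: boundary ranks, Betti numbers beta_{n,q}, Betti tables.

The Mayer Betti number is computed from the rank formula

    beta_{n,q} = dim C_n - rank(d_n^q) - rank(d_{n+N-q}^{N-q}),

with grades outside the built complex treated as zero spaces.  Two rank
backends are provided: an SVD-thresholded numeric rank (the main path) and
an exact rank over the cyclotomic field Q(xi) for prime N, used as a
certification oracle on small complexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import sympy as sp

from .chain_complex import NChain, Simplex, q_step_boundary
from .tolerances import DEFAULT_TOL, TolerancePolicy

__all__ = [
    "HomologySummary",
    "UnsupportedOracleError",
    "numeric_rank",
    "exact_rank",
    "exact_boundary_coeffs",
    "exact_q_step_rank",
    "mayer_betti",
    "betti_table",
    "betti_table_to_csv",
    "format_betti_table",
]


class UnsupportedOracleError(ValueError):
    """The exact cyclotomic oracle requires prime N (and exact weights)."""


@dataclass(frozen=True)
class HomologySummary:
    n: int
    q: int
    dim_Cn: int
    rank_dq: int
    rank_dNq: int

    @property
    def betti(self) -> int:
        return self.dim_Cn - self.rank_dq - self.rank_dNq


def numeric_rank(matrix: np.ndarray, tol: TolerancePolicy = DEFAULT_TOL) -> int:
    """Rank via singular values above the shared relative threshold."""
    M = np.asarray(matrix)
    if M.size == 0:
        return 0
    if not np.all(np.isfinite(M.real)) or not np.all(np.isfinite(M.imag)):
        raise ValueError("matrix has non-finite entries")
    s = np.linalg.svd(M, compute_uv=False)
    if s.size == 0:
        return 0
    return int(np.sum(s > tol.rank_threshold(M.shape, float(s[0]))))


# ---------------------------------------------------------------------------
# exact rank over Q(xi), N prime
# ---------------------------------------------------------------------------
#
# An element of Q(xi) is stored as its coordinate vector in the power basis
# 1, xi, ..., xi^{N-2} (N prime, so the minimal polynomial of xi is
# 1 + x + ... + x^{N-1}).  Restriction of scalars turns a matrix over Q(xi)
# into a rational matrix of (N-1)-fold size whose rank is (N-1) times the
# rank over Q(xi); sympy's fraction-free rational rank then decides exactly.


def _is_prime(n: int) -> bool:
    return n >= 2 and all(n % p for p in range(2, int(n ** 0.5) + 1))


def _companion(N: int) -> sp.Matrix:
    """Multiplication-by-xi matrix on the power basis of Q(xi), N prime."""
    C = sp.zeros(N - 1, N - 1)
    for i in range(N - 2):
        C[i + 1, i] = 1
    for i in range(N - 1):
        C[i, N - 2] = -1  # xi^{N-1} = -(1 + xi + ... + xi^{N-2})
    return C


def exact_rank(coeffs: Sequence, N: int) -> int:
    """Exact rank of a matrix over Q(xi) given in power-basis coordinates.

    ``coeffs[r][c]`` is the length-(N-1) rational coordinate vector of the
    (r, c) entry in the basis 1, xi, ..., xi^{N-2}.
    """
    if not _is_prime(N):
        raise UnsupportedOracleError(f"exact rank requires prime N, got {N}")
    rows = len(coeffs)
    cols = len(coeffs[0]) if rows else 0
    if rows == 0 or cols == 0:
        return 0
    d = N - 1
    C = _companion(N)
    powers = [sp.eye(d)]
    for _ in range(d - 1):
        powers.append(C * powers[-1])
    big = sp.zeros(rows * d, cols * d)
    for r in range(rows):
        for c in range(cols):
            vec = coeffs[r][c]
            block = sp.zeros(d, d)
            for t, coeff in enumerate(vec):
                if coeff:
                    block += sp.Rational(coeff) * powers[t]
            big[r * d:(r + 1) * d, c * d:(c + 1) * d] = block
    rk = big.rank()
    assert rk % d == 0, "restriction-of-scalars rank must be divisible by N-1"
    return rk // d


def exact_boundary_coeffs(chain: NChain, n: int, q: int) -> list[list[list[int]]]:
    """Power-basis coordinates of B_{n,q} for a unit-weight simplicial chain.

    Uses the closed-form entry ``alpha_q * xi^{[j]}`` expanded symbolically:
    ``alpha_q * xi^{[j]} = xi^{[j]-q(q-1)/2} * prod_k S(k)``, an element of
    Z[xi] reduced modulo 1 + x + ... + x^{N-1}.
    """
    N = chain.N
    if not _is_prime(N):
        raise UnsupportedOracleError(f"exact oracle requires prime N, got {N}")
    if chain.weight_kind != "unit":
        raise UnsupportedOracleError("exact oracle supports unit weights only")
    x = sp.Symbol("x")
    phi = sum(x ** k for k in range(N))
    # alpha_q as an exact polynomial in xi: shift by -q(q-1)/2 mod N
    from itertools import combinations

    prod = sp.Integer(1)
    for k in range(1, q + 1):
        prod *= sum(x ** i for i in range(k))
    shift = (-(q * (q - 1)) // 2) % N
    alpha_poly = sp.rem(sp.expand(prod * x ** shift), phi, x)

    rows = chain.basis(n - q) if n - q >= 0 else []
    cols = chain.basis(n)
    idx = {s: i for i, s in enumerate(rows)}
    d = N - 1
    out = [[[0] * d for _ in cols] for _ in rows]
    if n < q:
        return out
    for c, sigma in enumerate(cols):
        if not isinstance(sigma, Simplex):
            raise UnsupportedOracleError("exact oracle requires a simplicial chain")
        for j in combinations(range(len(sigma.vertices)), q):
            tau = sigma.face(j)
            entry = sp.rem(sp.expand(alpha_poly * x ** (sum(j) % N)), phi, x)
            poly = sp.Poly(entry, x)
            r = idx[tau]
            for t in range(d):
                out[r][c][t] += int(poly.coeff_monomial(x ** t))
    return out


def exact_q_step_rank(chain: NChain, n: int, q: int) -> int:
    """Exact rank of d_n^q over Q(xi) (prime N, unit weights)."""
    return exact_rank(exact_boundary_coeffs(chain, n, q), chain.N)


# ---------------------------------------------------------------------------
# Betti numbers
# ---------------------------------------------------------------------------


def mayer_betti(
    chain: NChain,
    n: int,
    q: int,
    tol: TolerancePolicy = DEFAULT_TOL,
    exact: bool = False,
) -> HomologySummary:
    """beta_{n,q} via the rank formula; grades above the built range vanish."""
    N = chain.N
    if not 1 <= q <= N - 1:
        raise ValueError(f"q must satisfy 1 <= q <= N-1 = {N - 1}, got {q}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if exact:
        r_dq = exact_q_step_rank(chain, n, q)
        r_dNq = exact_q_step_rank(chain, n + N - q, N - q)
    else:
        r_dq = numeric_rank(q_step_boundary(chain, n, q).matrix, tol)
        r_dNq = numeric_rank(q_step_boundary(chain, n + N - q, N - q).matrix, tol)
    return HomologySummary(n=n, q=q, dim_Cn=chain.dim(n), rank_dq=r_dq, rank_dNq=r_dNq)


def betti_table(
    chain: NChain,
    n_max: int | None = None,
    tol: TolerancePolicy = DEFAULT_TOL,
) -> dict[tuple[int, int], int]:
    """All nonzero beta_{n,q} for 0 <= n <= n_max, 1 <= q <= N-1."""
    if n_max is None:
        n_max = chain.top_dim
    out: dict[tuple[int, int], int] = {}
    for n in range(n_max + 1):
        for q in range(1, chain.N):
            b = mayer_betti(chain, n, q, tol).betti
            if b:
                out[(n, q)] = b
    return out


def betti_table_to_csv(table: dict[tuple[int, int], int]) -> str:
    lines = ["n,q,betti"]
    lines += [f"{n},{q},{b}" for (n, q), b in sorted(table.items())]
    return "\n".join(lines) + "\n"


def format_betti_table(table: dict[tuple[int, int], int]) -> str:
    """Human-readable listing, one ``beta_{n,q} = b`` per entry."""
    if not table:
        return "(no nonzero Mayer Betti numbers)"
    return ", ".join(f"beta_{{{n},{q}}} = {b}" for (n, q), b in sorted(table.items()))
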