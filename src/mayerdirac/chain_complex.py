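"""Mayer N-chain complexes over the complex numbers.

A Mayer N-chain complex is a graded vector space with boundary maps whose
N-fold composition vanishes (``d^N = 0``) while lower powers need not.  The
construction used throughout this package takes the boundary of an ordered
vertex tuple to be the alternating-by-root-of-unity sum

    d (v_0, ..., v_n) = sum_i  xi^i  (v_0, ..., v_{i-1}, v_{i+1}, ..., v_n)

with ``xi = exp(2 pi i / N)`` a primitive N-th root of unity.  For N = 2
this is the classical simplicial boundary (``xi = -1``); for N > 2 the
complex carries Mayer homology groups H_{n,q} for 1 <= q <= N - 1.

Two complexes are provided:

* the *simplicial* N-subchain spanned by strictly increasing vertex tuples
  of a simplicial complex (the default for all applications), and
* the *full tuple* complex on V^{n+1} (repeats allowed), used for
  verification only since it grows geometrically.

All matrices are stored with respect to the weighted orthonormal basis
``{sigma / w_sigma}`` induced by the inner product
``<lambda sigma, mu tau> = lambda conj(mu) w_sigma^2 delta_{sigma,tau}``.
"""

from __future__ import annotations

import cmath
import json
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CyclotomicContext",
    "Simplex",
    "WeightScheme",
    "NChain",
    "QStepBoundary",
    "FaceClosureError",
    "BasisSizeError",
    "make_context",
    "build_simplicial_nchain",
    "build_tensor_nchain",
    "q_step_boundary",
    "q_step_entrywise",
    "save_nchain",
    "load_nchain",
]

#: hard ceiling on basis elements per grade for the full tuple complex
TENSOR_BASIS_CAP = 20_000


class FaceClosureError(ValueError):
    """A simplex list is missing one of its faces."""


class BasisSizeError(ValueError):
    """A requested full tuple complex would exceed the basis-size cap."""


# ---------------------------------------------------------------------------
# cyclotomic context
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CyclotomicContext:
    """Order N, the primitive root xi = e^{2 pi i/N}, and the alpha_q table.

    ``alpha[q] = xi^{-q(q-1)/2} * prod_{k=1}^{q} (1 + xi + ... + xi^{k-1})``
    is the nonzero scalar relating the q-fold boundary product to the
    position-weight sum over removed index tuples.
    """

    N: int
    xi: complex
    alpha: Mapping[int, complex]

    def xi_pow(self, k: int) -> complex:
        """xi^k, reduced mod N for numerical stability."""
        return cmath.exp(2j * cmath.pi * (k % self.N) / self.N)

    def partial_sum(self, k: int) -> complex:
        """S(k) = 1 + xi + ... + xi^{k-1}."""
        return sum(self.xi_pow(i) for i in range(k))


def make_context(N: int) -> CyclotomicContext:
    """Build the cyclotomic context for order ``N >= 2``."""
    if not isinstance(N, (int, np.integer)) or isinstance(N, bool) or N < 2:
        raise ValueError(f"N must be an integer >= 2, got {N!r}")
    N = int(N)
    xi = cmath.exp(2j * cmath.pi / N)
    alpha: dict[int, complex] = {}
    for q in range(1, N):
        prod = 1.0 + 0.0j
        for k in range(1, q + 1):
            prod *= sum(xi ** i for i in range(k))
        alpha[q] = xi ** (-(q * (q - 1)) // 2) * prod
    return CyclotomicContext(N=N, xi=xi, alpha=dict(alpha))


# ---------------------------------------------------------------------------
# simplices and weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Simplex:
    """A simplex given by its strictly increasing vertex tuple."""

    vertices: tuple[int, ...]

    def __post_init__(self) -> None:
        v = self.vertices
        if not isinstance(v, tuple):
            object.__setattr__(self, "vertices", tuple(v))
            v = self.vertices
        if any(a >= b for a, b in zip(v, v[1:])):
            raise ValueError(f"vertices must be strictly increasing, got {v}")
        if len(v) == 0:
            raise ValueError("a simplex needs at least one vertex")

    @property
    def dim(self) -> int:
        return len(self.vertices) - 1

    def face(self, positions: Sequence[int]) -> "Simplex":
        """Remove the vertices at the given positions (sigma^j)."""
        drop = set(positions)
        return Simplex(tuple(v for i, v in enumerate(self.vertices) if i not in drop))

    def facets(self) -> list["Simplex"]:
        """All codimension-1 faces, in removal-position order."""
        return [self.face((i,)) for i in range(len(self.vertices))] if self.dim > 0 else []


class WeightScheme:
    """Positive weights w_sigma defining the inner product ``w_sigma^2``.

    ``unit``               : w_sigma = 1 everywhere.
    ``simplex-mean-distance``: w_sigma = mean pairwise Euclidean distance of
                             the simplex's vertex coordinates for dim >= 1,
                             w = 1 for vertices.  With ``squared=True`` the
                             squared mean distance is used instead; both
                             readings of the weighting recipe are exposed.
    ``user-table``         : explicit simplex -> weight table.
    """

    def __init__(self, kind: str, fn: Callable[[Simplex], float]):
        self.kind = kind
        self._fn = fn

    def weight(self, simplex: Simplex) -> float:
        w = float(self._fn(simplex))
        if not (w > 0.0) or not np.isfinite(w):
            raise ValueError(f"weight for {simplex.vertices} must be positive and finite, got {w}")
        return w

    @classmethod
    def unit(cls) -> "WeightScheme":
        return cls("unit", lambda s: 1.0)

    @classmethod
    def from_table(cls, table: Mapping[tuple[int, ...], float]) -> "WeightScheme":
        tbl = {tuple(k): float(v) for k, v in table.items()}

        def fn(s: Simplex) -> float:
            try:
                return tbl[s.vertices]
            except KeyError:
                raise KeyError(f"no weight for simplex {s.vertices}") from None

        return cls("user-table", fn)

    @classmethod
    def mean_distance(cls, coordinates: np.ndarray, squared: bool = False) -> "WeightScheme":
        coords = np.asarray(coordinates, dtype=float)

        def fn(s: Simplex) -> float:
            if s.dim == 0:
                return 1.0
            pts = coords[list(s.vertices)]
            d = [float(np.linalg.norm(a - b)) for a, b in combinations(pts, 2)]
            m = float(np.mean(d))
            if m <= 0.0:
                # coincident points: fall back to unit weight so the inner
                # product stays positive definite
                return 1.0
            return m * m if squared else m

        return cls("simplex-mean-distance", fn)


# ---------------------------------------------------------------------------
# the chain itself
# ---------------------------------------------------------------------------


@dataclass
class NChain:
    """Graded bases, weights, and single-step boundary matrices.

    ``bases[n]`` is the ordered simplex list of grade n (empty grades are
    simply absent); ``B[n]`` represents d_n on the weighted orthonormal
    bases and has shape ``(dim C_{n-1}, dim C_n)``.  Grades outside the
    built range are zero spaces.
    """

    context: CyclotomicContext
    bases: dict[int, list[Simplex]]
    weights: dict[Simplex, float]
    B: dict[int, np.ndarray] = field(default_factory=dict)
    weight_kind: str = "unit"

    @property
    def N(self) -> int:
        return self.context.N

    @property
    def top_dim(self) -> int:
        return max(self.bases) if self.bases else -1

    def dim(self, n: int) -> int:
        return len(self.bases.get(n, ()))

    def basis(self, n: int) -> list[Simplex]:
        return list(self.bases.get(n, ()))

    def weight(self, simplex: Simplex) -> float:
        return self.weights[simplex]

    def weight_diag(self, n: int) -> np.ndarray:
        return np.diag([self.weights[s] for s in self.bases.get(n, ())])

    def boundary(self, n: int) -> np.ndarray:
        """B_n for any n >= 0 (zero-shaped outside the built range)."""
        if n in self.B:
            return self.B[n]
        return np.zeros((self.dim(n - 1) if n >= 1 else 0, self.dim(n)), dtype=complex)

    def index(self, n: int, simplex: Simplex) -> int:
        return self.bases[n].index(simplex)


def _validate_face_closed(simplices: Iterable[Simplex]) -> list[Simplex]:
    present = set(simplices)
    if not present:
        raise ValueError("empty simplex list")
    for s in present:
        for f in s.facets():
            if f not in present:
                raise FaceClosureError(
                    f"simplex list is not face-closed: {s.vertices} is present "
                    f"but its face {f.vertices} is missing"
                )
    return sorted(present, key=lambda s: (s.dim, s.vertices))


def build_simplicial_nchain(
    simplices: Iterable[Simplex | Sequence[int]],
    context: CyclotomicContext,
    weights: WeightScheme | None = None,
) -> NChain:
    """Build the Mayer N-chain of a face-closed simplicial complex.

    Bases are sorted lexicographically by vertex tuple within each
    dimension.  The single-step boundary entry for the face tau obtained by
    removing position i from sigma is ``(w_tau / w_sigma) * xi^i``.
    """
    weights = weights or WeightScheme.unit()
    simps = [s if isinstance(s, Simplex) else Simplex(tuple(s)) for s in simplices]
    ordered = _validate_face_closed(simps)

    bases: dict[int, list[Simplex]] = {}
    for s in ordered:
        bases.setdefault(s.dim, []).append(s)

    wtab = {s: weights.weight(s) for s in ordered}
    chain = NChain(context=context, bases=bases, weights=wtab, weight_kind=weights.kind)

    xi = context.xi
    for n in sorted(bases):
        if n == 0:
            continue
        lower = bases.get(n - 1, [])
        idx = {s: i for i, s in enumerate(lower)}
        M = np.zeros((len(lower), len(bases[n])), dtype=complex)
        for col, sigma in enumerate(bases[n]):
            for i in range(len(sigma.vertices)):
                tau = sigma.face((i,))
                M[idx[tau], col] += (wtab[tau] / wtab[sigma]) * xi ** i
        chain.B[n] = M
    return chain


def build_tensor_nchain(
    vertex_count: int,
    n_max: int,
    context: CyclotomicContext,
    basis_cap: int = TENSOR_BASIS_CAP,
) -> NChain:
    """Full tuple complex on V^{n+1} (repeats allowed) up to grade n_max.

    Verification construction only: basis size grows as |V|^{n+1} and is
    capped.  Boundary entries sum xi^i over every removal position that
    produces the target tuple.
    """
    if vertex_count < 1 or n_max < 0:
        raise ValueError("vertex_count >= 1 and n_max >= 0 required")
    if vertex_count ** (n_max + 1) > basis_cap:
        raise BasisSizeError(
            f"|V|^(n+1) = {vertex_count ** (n_max + 1)} exceeds the cap {basis_cap}"
        )
    verts = range(vertex_count)
    bases: dict[int, list[tuple[int, ...]]] = {
        n: sorted(product(verts, repeat=n + 1)) for n in range(n_max + 1)
    }
    # tuples are not Simplex instances (repeats allowed); NChain stores them
    # behind the same interface with unit weights
    chain = NChain(
        context=context,
        bases=bases,  # type: ignore[arg-type]
        weights={t: 1.0 for b in bases.values() for t in b},  # type: ignore[misc]
        weight_kind="unit",
    )
    xi = context.xi
    for n in range(1, n_max + 1):
        lower = bases[n - 1]
        idx = {t: i for i, t in enumerate(lower)}
        M = np.zeros((len(lower), len(bases[n])), dtype=complex)
        for col, v in enumerate(bases[n]):
            for i in range(len(v)):
                tau = v[:i] + v[i + 1:]
                M[idx[tau], col] += xi ** i
        chain.B[n] = M
    return chain


# ---------------------------------------------------------------------------
# q-step boundaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QStepBoundary:
    """The q-fold boundary product B_{n,q} = B_{n-q+1} ... B_n."""

    n: int
    q: int
    matrix: np.ndarray


def q_step_boundary(chain: NChain, n: int, q: int) -> QStepBoundary:
    """Representation matrix of d_n^q; zero when n < q (d_0 = 0)."""
    N = chain.N
    if not 1 <= q <= N - 1:
        raise ValueError(f"q must satisfy 1 <= q <= N-1 = {N - 1}, got {q}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rows = chain.dim(n - q) if n - q >= 0 else 0
    if n < q:
        return QStepBoundary(n, q, np.zeros((rows, chain.dim(n)), dtype=complex))
    M = np.eye(chain.dim(n), dtype=complex)
    for m in range(n, n - q, -1):
        M = chain.boundary(m) @ M
    return QStepBoundary(n, q, M)


def q_step_entrywise(chain: NChain, n: int, q: int) -> np.ndarray:
    """Direct closed-form assembly of B_{n,q} for simplicial chains.

    Entry (tau, sigma) is ``(w_tau/w_sigma) * alpha_q * xi^{[j]}`` where j
    is the unique increasing position tuple with sigma^j = tau, and
    ``[j] = j_1 + ... + j_q``.  Independent of the matrix-product route;
    used to certify it.
    """
    if not 1 <= q <= chain.N - 1:
        raise ValueError(f"q must satisfy 1 <= q <= N-1, got {q}")
    rows = chain.basis(n - q) if n - q >= 0 else []
    cols = chain.basis(n)
    if not all(isinstance(s, Simplex) for s in cols):
        raise TypeError("entrywise formula requires a simplicial chain")
    M = np.zeros((len(rows), len(cols)), dtype=complex)
    if n < q:
        return M
    alpha_q = chain.context.alpha[q]
    idx = {s: i for i, s in enumerate(rows)}
    for col, sigma in enumerate(cols):
        for j in combinations(range(len(sigma.vertices)), q):
            tau = sigma.face(j)
            M[idx[tau], col] += (
                chain.weight(tau) / chain.weight(sigma) * alpha_q * chain.context.xi_pow(sum(j))
            )
    return M


# ---------------------------------------------------------------------------
# serialization (checkpointing for persistence runs)
# ---------------------------------------------------------------------------
#
# Archive layout: a single JSON document with
#   N                 : int
#   weight_kind       : str
#   bases             : {str(n): [[v0, v1, ...], ...]}
#   weights           : {str(n): [w, ...]}     (aligned with bases[n])
#   boundaries        : {str(n): {"real": [[...]], "imag": [[...]]}}


def save_nchain(chain: NChain, path: str | Path) -> None:
    doc = {
        "N": chain.N,
        "weight_kind": chain.weight_kind,
        "bases": {
            str(n): [list(s.vertices) for s in chain.bases[n]] for n in sorted(chain.bases)
        },
        "weights": {
            str(n): [chain.weights[s] for s in chain.bases[n]] for n in sorted(chain.bases)
        },
        "boundaries": {
            str(n): {"real": chain.B[n].real.tolist(), "imag": chain.B[n].imag.tolist()}
            for n in sorted(chain.B)
        },
    }
    Path(path).write_text(json.dumps(doc))


def load_nchain(path: str | Path) -> NChain:
    doc = json.loads(Path(path).read_text())
    context = make_context(int(doc["N"]))
    bases = {
        int(n): [Simplex(tuple(v)) for v in rows] for n, rows in doc["bases"].items()
    }
    weights: dict[Simplex, float] = {}
    for n, ws in doc["weights"].items():
        for s, w in zip(bases[int(n)], ws):
            weights[s] = float(w)
    chain = NChain(
        context=context, bases=bases, weights=weights, weight_kind=doc["weight_kind"]
    )
    for n, mat in doc["boundaries"].items():
        chain.B[int(n)] = np.asarray(mat["real"], dtype=float) + 1j * np.asarray(
            mat["imag"], dtype=float
        )
    return chain
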