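"""Vietoris-Rips filtrations and persistent Mayer operators.

A labeled point cloud (atoms as points in space) induces a Vietoris-Rips
flag filtration: a simplex is present at scale t when every pairwise
distance among its vertices is at most t.  Each filtration step carries a
Mayer N-chain complex; for a pair of steps x <= y with complexes A and B,
the package computes

* persistent Mayer Betti numbers, the rank of the map
  H_{n,q}(A) -> H_{n,q}(B) induced by inclusion,
* the persistent Mayer Laplacian, whose kernel realizes the persistent
  homology, built by compressing the (N-q)-step boundary of B to the
  preimage subspace {x in B_{n+N-q} : b^{N-q} x in A_n}, and
* the persistent Mayer Dirac operator, the Dirac operator of the auxiliary
  complex C_{0,i,q} = B_i, C_{n,i,q} = (b^{step})^{-1}(A_{t_{n-1}}).

All reported quantities (spectra, nullities) are invariant under the
orthonormal basis choices made for the preimage subspaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .chain_complex import (
    CyclotomicContext,
    NChain,
    Simplex,
    WeightScheme,
    build_simplicial_nchain,
    q_step_boundary,
)
from .spectral import _t_index, dirac_matrix, mayer_laplacian, spectrum
from .tolerances import DEFAULT_TOL, TolerancePolicy

__all__ = [
    "PointCloud",
    "Filtration",
    "PersistentPairOperators",
    "rips_filtration",
    "element_filter",
    "persistent_betti",
    "persistent_betti_subspace",
    "persistent_laplacian",
    "persistent_dirac",
    "persistence_curves",
]


@dataclass(frozen=True)
class PointCloud:
    """Atomic point cloud; the point index defines the vertex total order."""

    coordinates: np.ndarray  # (m, 3) in Angstrom
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if coords.size == 0:
            coords = coords.reshape(0, 3)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "labels", tuple(str(l).capitalize() for l in self.labels))
        if len(self.labels) != len(coords):
            raise ValueError("one label per point required")

    def __len__(self) -> int:
        return len(self.labels)

    def distance_matrix(self) -> np.ndarray:
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt(np.sum(diff * diff, axis=-1))


def element_filter(cloud: PointCloud, symbol: str) -> PointCloud:
    """Restrict to the points carrying the given element symbol."""
    symbol = str(symbol).capitalize()
    keep = [i for i, l in enumerate(cloud.labels) if l == symbol]
    if not keep:
        warnings.warn(f"element {symbol!r} not present in the cloud; returning empty cloud")
        return PointCloud(np.zeros((0, 3)), ())
    return PointCloud(cloud.coordinates[keep], tuple(cloud.labels[i] for i in keep))


# ---------------------------------------------------------------------------
# filtration construction
# ---------------------------------------------------------------------------


@dataclass
class Filtration:
    """A monotone grid of scales with one nested N-chain per grid value."""

    grid: np.ndarray
    chains: list[NChain]
    context: CyclotomicContext
    weight_kind: str = "unit"
    simplex_values: dict[tuple[int, ...], float] = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.context.N

    def index_of(self, x: float) -> int:
        hits = np.flatnonzero(np.isclose(self.grid, x, rtol=0.0, atol=1e-9))
        if hits.size == 0:
            raise ValueError(f"{x} is not on the filtration grid {self.grid}")
        return int(hits[0])

    def chain_at(self, x: float) -> NChain:
        return self.chains[self.index_of(x)]

    def summary(self) -> dict:
        return {
            "N": self.N,
            "weight_kind": self.weight_kind,
            "grid": [float(g) for g in self.grid],
            "basis_sizes": [
                {str(n): c.dim(n) for n in sorted(c.bases)} for c in self.chains
            ],
        }


def _rips_simplices(
    dist: np.ndarray, r_max: float, max_dim: int
) -> dict[tuple[int, ...], float]:
    """Simplices of the flag complex at scale r_max with entry scales.

    A simplex enters at the length of its longest edge (its diameter).
    """
    m = dist.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(m))
    for a in range(m):
        for b in range(a + 1, m):
            if dist[a, b] <= r_max + 1e-12:
                g.add_edge(a, b)
    values: dict[tuple[int, ...], float] = {}
    for clique in nx.enumerate_all_cliques(g):
        if len(clique) > max_dim + 1:
            break
        verts = tuple(sorted(clique))
        diam = 0.0
        for ia, a in enumerate(verts):
            for b in verts[ia + 1:]:
                diam = max(diam, float(dist[a, b]))
        values[verts] = diam
    return values


def rips_filtration(
    cloud: PointCloud,
    r_min: float = 0.0,
    r_max: float = 7.0,
    steps: int = 28,
    max_dim: int = 2,
    context: CyclotomicContext | None = None,
    weights: str | WeightScheme = "unit",
    grid: Sequence[float] | None = None,
) -> Filtration:
    """Vietoris-Rips filtration of a point cloud as nested Mayer N-chains.

    The default grid places ``steps`` uniform values on (r_min, r_max]
    (28 values at 0.25 Angstrom spacing for the 0-7 Angstrom default).
    ``weights`` is ``"unit"``, ``"mean-dist"`` (simplex mean pairwise
    distance, vertices at 1), or an explicit :class:`WeightScheme`.
    """
    if context is None:
        raise ValueError("a CyclotomicContext is required (make_context(N))")
    if grid is None:
        if steps < 1 or r_min > r_max:
            raise ValueError("steps >= 1 and r_min <= r_max required")
        step = (r_max - r_min) / steps
        grid_arr = r_min + step * np.arange(1, steps + 1)
    else:
        grid_arr = np.asarray(sorted(float(g) for g in grid))
        if grid_arr.size == 0 or np.any(np.diff(grid_arr) <= 0):
            raise ValueError("grid must be nonempty and strictly increasing")
    if max_dim < 0:
        raise ValueError("max_dim must be >= 0")

    if isinstance(weights, WeightScheme):
        scheme = weights
    elif weights == "unit":
        scheme = WeightScheme.unit()
    elif weights in ("mean-dist", "simplex-mean-distance"):
        scheme = WeightScheme.mean_distance(cloud.coordinates)
    else:
        raise ValueError(f"unknown weight scheme {weights!r}")

    values = (
        _rips_simplices(cloud.distance_matrix(), float(grid_arr[-1]), max_dim)
        if len(cloud)
        else {}
    )
    chains: list[NChain] = []
    for t in grid_arr:
        present = [Simplex(v) for v, f in values.items() if f <= t + 1e-12]
        if present:
            chains.append(build_simplicial_nchain(present, context, scheme))
        else:
            chains.append(NChain(context=context, bases={}, weights={}, weight_kind=scheme.kind))
    return Filtration(
        grid=grid_arr,
        chains=chains,
        context=context,
        weight_kind=scheme.kind,
        simplex_values=values,
    )


# ---------------------------------------------------------------------------
# subspace utilities
# ---------------------------------------------------------------------------


def _null_basis(M: np.ndarray, tol: TolerancePolicy) -> np.ndarray:
    """Orthonormal null-space basis with the shared rank threshold."""
    rows, cols = M.shape
    if cols == 0:
        return np.zeros((0, 0), dtype=complex)
    if rows == 0:
        return np.eye(cols, dtype=complex)
    u, s, vh = np.linalg.svd(M)
    thr = tol.rank_threshold(M.shape, float(s[0]) if s.size else 0.0)
    rank = int(np.sum(s > thr))
    return vh[rank:].conj().T


def _col_basis(M: np.ndarray, tol: TolerancePolicy) -> np.ndarray:
    """Orthonormal column-space basis with the shared rank threshold."""
    rows, cols = M.shape
    if rows == 0 or cols == 0:
        return np.zeros((rows, 0), dtype=complex)
    u, s, vh = np.linalg.svd(M, full_matrices=False)
    thr = tol.rank_threshold(M.shape, float(s[0]) if s.size else 0.0)
    rank = int(np.sum(s > thr))
    return u[:, :rank]


def _inclusion(sub: list, full: list) -> np.ndarray:
    """0/1 matrix embedding the subcomplex basis into the full basis."""
    pos = {s: i for i, s in enumerate(full)}
    P = np.zeros((len(full), len(sub)), dtype=complex)
    for j, s in enumerate(sub):
        P[pos[s], j] = 1.0
    return P


@dataclass(frozen=True)
class PersistentPairOperators:
    """A persistent operator with its index metadata and derived Betti."""

    x: float
    y: float
    indices: tuple[int, ...]  # (n, q) or (k, i, q)
    matrix: np.ndarray
    block_sizes: tuple[int, ...] | None = None

    def persistent_betti(self, tol: TolerancePolicy = DEFAULT_TOL) -> int:
        return spectrum(self.matrix, tol).nullity


# ---------------------------------------------------------------------------
# persistent Laplacian and Betti
# ---------------------------------------------------------------------------


def persistent_laplacian(
    filtration: Filtration,
    x: float,
    y: float,
    n: int,
    q: int,
    tol: TolerancePolicy = DEFAULT_TOL,
) -> PersistentPairOperators:
    """The (x, y)-persistent Mayer Laplacian on A_n (A at scale x, B at y).

    Down term: the q-step boundary of A itself.  Up term: the (N-q)-step
    boundary of B compressed to an orthonormal basis of the preimage
    subspace {v in B_{n+N-q} : b^{N-q} v in A_n}; for n < q the Down term
    vanishes (d^q = 0 below grade q).
    """
    ix, iy = filtration.index_of(x), filtration.index_of(y)
    if ix > iy:
        raise ValueError("x must be <= y on the grid")
    A, B = filtration.chains[ix], filtration.chains[iy]
    N = filtration.N
    if not 1 <= q <= N - 1:
        raise ValueError(f"q out of range [1, {N - 1}]: {q}")

    Dq = q_step_boundary(A, n, q).matrix
    down = Dq.conj().T @ Dq

    R = q_step_boundary(B, n + N - q, N - q).matrix  # B_{n+N-q} -> B_n
    basisA, basisB = A.basis(n), B.basis(n)
    P = _inclusion(basisA, basisB)
    outside = [i for i, s in enumerate(basisB) if s not in set(basisA)]
    constraint = R[outside, :] if outside else np.zeros((0, R.shape[1]))
    Y = _null_basis(constraint, tol)  # preimage subspace basis
    Mup = P.conj().T @ R @ Y  # lands in A_n by construction
    up = Mup @ Mup.conj().T
    return PersistentPairOperators(
        x=float(filtration.grid[ix]),
        y=float(filtration.grid[iy]),
        indices=(n, q),
        matrix=down + up,
    )


def persistent_betti_subspace(
    filtration: Filtration,
    x: float,
    y: float,
    n: int,
    q: int,
    tol: TolerancePolicy = DEFAULT_TOL,
) -> int:
    """Independent subspace route to the persistent Mayer Betti number.

    beta^{x,y}_{n,q} = dim Z_{n,q}(A) - dim( Z_{n,q}(A) /\\ im b^{N-q}(B) ),
    with the intersection dimension obtained from the rank of the stacked
    orthonormal bases.
    """
    ix, iy = filtration.index_of(x), filtration.index_of(y)
    if ix > iy:
        raise ValueError("x must be <= y on the grid")
    A, B = filtration.chains[ix], filtration.chains[iy]
    N = filtration.N
    Z = _null_basis(q_step_boundary(A, n, q).matrix, tol)  # in A_n coords
    P = _inclusion(A.basis(n), B.basis(n))
    Zb = P @ Z  # cycles of A inside B_n
    Im = _col_basis(q_step_boundary(B, n + N - q, N - q).matrix, tol)
    dz, di = Zb.shape[1], Im.shape[1]
    if dz == 0:
        return 0
    if di == 0:
        return dz
    stacked = np.hstack([Zb, Im])
    from .homology import numeric_rank

    inter = dz + di - numeric_rank(stacked, tol)
    return dz - inter


def persistent_betti(
    filtration: Filtration,
    x: float,
    y: float,
    n: int,
    q: int,
    tol: TolerancePolicy = DEFAULT_TOL,
    method: str = "laplacian",
) -> int:
    """Persistent Mayer Betti number via the chosen backend."""
    if method == "laplacian":
        return persistent_laplacian(filtration, x, y, n, q, tol).persistent_betti(tol)
    if method == "subspace":
        return persistent_betti_subspace(filtration, x, y, n, q, tol)
    raise ValueError(f"unknown method {method!r}; use 'laplacian' or 'subspace'")


# ---------------------------------------------------------------------------
# persistent Dirac
# ---------------------------------------------------------------------------


def persistent_dirac(
    filtration: Filtration,
    x: float,
    y: float,
    k: int,
    i: int,
    q: int,
    tol: TolerancePolicy = DEFAULT_TOL,
) -> PersistentPairOperators:
    """The (x, y)-persistent Mayer Dirac D^{A,B}_{k,i,q}.

    Auxiliary grades: C_0 = B at grade i; C_m for m >= 1 is the preimage in
    B of A's grade t_{m-1} under the alternating q-/(N-q)-step boundary of
    B.  Each grade is realized as an orthonormal subspace basis, and the
    boundary maps are compressed to those bases.  At x = y the subspaces
    are the full spaces and the operator is unitarily equivalent to the
    non-persistent Dirac.
    """
    ix, iy = filtration.index_of(x), filtration.index_of(y)
    if ix > iy:
        raise ValueError("x must be <= y on the grid")
    A, B = filtration.chains[ix], filtration.chains[iy]
    N = filtration.N
    if not 1 <= q <= N - 1:
        raise ValueError(f"q out of range [1, {N - 1}]: {q}")
    if not 0 <= i < N - q:
        raise ValueError(f"i must satisfy 0 <= i < N-q = {N - q}, got {i}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")

    grades = [_t_index(i, q, N, j) for j in range(k + 2)]
    bases_Y: list[np.ndarray] = [np.eye(B.dim(grades[0]), dtype=complex)]
    maps_c: list[np.ndarray] = []
    for m in range(1, k + 2):
        step = q if m % 2 else N - q
        t_m, t_prev = grades[m], grades[m - 1]
        R = q_step_boundary(B, t_m, step).matrix  # B_{t_m} -> B_{t_prev}
        basisA_prev, basisB_prev = A.basis(t_prev), B.basis(t_prev)
        outside = [j for j, s in enumerate(basisB_prev) if s not in set(basisA_prev)]
        constraint = R[outside, :] if outside else np.zeros((0, R.shape[1]))
        Y = _null_basis(constraint, tol)
        bases_Y.append(Y)
        maps_c.append(bases_Y[m - 1].conj().T @ R @ Y)

    sizes = tuple(Y.shape[1] for Y in bases_Y)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    total = int(offsets[-1])
    D = np.zeros((total, total), dtype=complex)
    for m in range(1, k + 2):
        r = slice(int(offsets[m - 1]), int(offsets[m]))
        c = slice(int(offsets[m]), int(offsets[m + 1]))
        D[r, c] = maps_c[m - 1]
        D[c, r] = maps_c[m - 1].conj().T
    return PersistentPairOperators(
        x=float(filtration.grid[ix]),
        y=float(filtration.grid[iy]),
        indices=(k, i, q),
        matrix=D,
        block_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------


def persistence_curves(
    filtration: Filtration,
    feature_names: Sequence[str] | None = None,
    k: int = 0,
    i: int = 0,
    q: int = 1,
    mode: str = "single",
    tol: TolerancePolicy = DEFAULT_TOL,
) -> pd.DataFrame:
    """Spectral feature curves of (persistent) Mayer Dirac operators.

    ``mode="single"`` evaluates the Dirac of each step's own complex;
    ``mode="pairs"`` evaluates the persistent Dirac of consecutive grid
    pairs (x_j, x_{j+1}).  One row per grid point; an empty filtration
    (no simplices anywhere) yields an empty table.
    """
    from .features import FEATURE_NAMES, feature_vector, spectral_features

    names = list(feature_names) if feature_names is not None else list(FEATURE_NAMES)
    unknown = [f for f in names if f not in FEATURE_NAMES + ("c1_sign", "c1_log_magnitude")]
    if unknown:
        raise ValueError(
            f"unknown feature(s) {unknown}; known: {list(FEATURE_NAMES)}"
        )
    if mode not in ("single", "pairs"):
        raise ValueError("mode must be 'single' or 'pairs'")
    if all(sum(c.dim(n) for n in c.bases) == 0 for c in filtration.chains):
        return pd.DataFrame(columns=["x", "y", "k", "i", "q", *names])

    rows = []
    m = len(filtration.grid)
    for j in range(m):
        x = float(filtration.grid[j])
        if mode == "single":
            y = x
            D = dirac_matrix(filtration.chains[j], k, i, q).matrix
        else:
            if j + 1 >= m:
                break
            y = float(filtration.grid[j + 1])
            D = persistent_dirac(filtration, x, y, k, i, q, tol).matrix
        spec = spectrum(D, tol)
        feats = spectral_features(spec.eigenvalues, dimension=D.shape[0], tol=tol)
        rows.append([x, y, k, i, q, *feature_vector(feats, names)])
    return pd.DataFrame(rows, columns=["x", "y", "k", "i", "q", *names])
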