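"""Independent classical simplicial homology oracle for N=2 cross-checks.

Deliberately separate from the package: real arithmetic, (-1)^i boundary
signs, numpy matrix_rank.  Used to certify that the root-of-unity
construction at N=2 reduces to ordinary simplicial (persistent) homology.
"""

from __future__ import annotations

import numpy as np


def _sorted_bases(simplices):
    by_dim: dict[int, list[tuple[int, ...]]] = {}
    for s in simplices:
        t = tuple(s)
        by_dim.setdefault(len(t) - 1, []).append(t)
    return {n: sorted(set(v)) for n, v in by_dim.items()}


def classical_boundary(simplices, n: int) -> np.ndarray:
    """Real boundary matrix of grade n with (-1)^i signs."""
    bases = _sorted_bases(simplices)
    rows = bases.get(n - 1, [])
    cols = bases.get(n, [])
    idx = {s: i for i, s in enumerate(rows)}
    M = np.zeros((len(rows), len(cols)))
    for c, s in enumerate(cols):
        for i in range(len(s)):
            face = s[:i] + s[i + 1:]
            M[idx[face], c] += (-1.0) ** i
    return M


def classical_betti(simplices, n: int) -> int:
    bases = _sorted_bases(simplices)
    dim_n = len(bases.get(n, []))
    r_n = np.linalg.matrix_rank(classical_boundary(simplices, n)) if n >= 1 else 0
    r_up = np.linalg.matrix_rank(classical_boundary(simplices, n + 1))
    return dim_n - r_n - r_up


def _null_space(M: np.ndarray) -> np.ndarray:
    if M.shape[1] == 0:
        return np.zeros((0, 0))
    if M.shape[0] == 0:
        return np.eye(M.shape[1])
    _, s, vh = np.linalg.svd(M)
    rank = int(np.sum(s > max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0)))
    return vh[rank:].T


def classical_persistent_betti(simplices_a, simplices_b, n: int) -> int:
    """dim Z_n(A) - dim(Z_n(A) /\\ B_n(B)) via ranks of stacked bases."""
    bases_a = _sorted_bases(simplices_a)
    bases_b = _sorted_bases(simplices_b)
    basis_an = bases_a.get(n, [])
    basis_bn = bases_b.get(n, [])
    Z = _null_space(classical_boundary(simplices_a, n)) if n >= 1 else np.eye(len(basis_an))
    # embed A-cycles into B's grade-n coordinates
    pos = {s: i for i, s in enumerate(basis_bn)}
    P = np.zeros((len(basis_bn), len(basis_an)))
    for j, s in enumerate(basis_an):
        P[pos[s], j] = 1.0
    Zb = P @ Z
    Bnd = classical_boundary(simplices_b, n + 1)
    dz = Zb.shape[1]
    di = np.linalg.matrix_rank(Bnd) if Bnd.size else 0
    if dz == 0:
        return 0
    if di == 0:
        return dz
    stacked = np.hstack([Zb, Bnd])
    inter = dz + di - np.linalg.matrix_rank(stacked)
    return dz - inter
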