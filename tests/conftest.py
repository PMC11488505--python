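from __future__ import annotations

import numpy as np
import pytest

from mayerdirac import (
    PointCloud,
    Simplex,
    build_simplicial_nchain,
    make_context,
    standard_simplex_complex,
)


@pytest.fixture(scope="session")
def ctx2():
    return make_context(2)


@pytest.fixture(scope="session")
def ctx3():
    return make_context(3)


@pytest.fixture(scope="session")
def ctx5():
    return make_context(5)


@pytest.fixture(scope="session")
def triangle3(ctx3):
    """The 3-chain of the full 2-simplex (the worked example complex)."""
    return build_simplicial_nchain(standard_simplex_complex(2), ctx3)


@pytest.fixture(scope="session")
def tetra3(ctx3):
    return build_simplicial_nchain(standard_simplex_complex(3), ctx3)


def random_flag_complex(seed: int, n_points: int = 5, radius: float = 1.2):
    """Seeded random flag complex: threshold graph of a random cloud + cliques."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, 2.0, size=(n_points, 3))
    import itertools

    simplices = [Simplex((i,)) for i in range(n_points)]
    edges = [
        (a, b)
        for a, b in itertools.combinations(range(n_points), 2)
        if np.linalg.norm(pts[a] - pts[b]) <= radius
    ]
    adj = {i: set() for i in range(n_points)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    for size in range(2, n_points + 1):
        for combo in itertools.combinations(range(n_points), size):
            if all(b in adj[a] for a, b in itertools.combinations(combo, 2)):
                simplices.append(Simplex(combo))
    return simplices, pts


@pytest.fixture(scope="session")
def random_cloud6():
    rng = np.random.default_rng(42)
    return PointCloud(rng.uniform(0.0, 2.5, size=(6, 3)), ("X",) * 6)
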