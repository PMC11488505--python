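from __future__ import annotations

import numpy as np
import pytest

from mayerdirac import (
    PointCloud,
    dirac_matrix,
    element_filter,
    make_context,
    mayer_betti,
    mayer_laplacian,
    persistence_curves,
    persistent_betti,
    persistent_dirac,
    persistent_laplacian,
    rips_filtration,
    spectrum,
)
from mayerdirac.persistence import persistent_betti_subspace

from _classical import classical_persistent_betti


def _two_point_cloud():
    return PointCloud(np.array([[0.0, 0, 0], [2.0, 0, 0]]), ("X", "X"))


def test_rips_threshold_crossing(ctx2):
    """Two points at distance 2: vertices at t=1, one edge at t=3."""
    filt = rips_filtration(_two_point_cloud(), grid=[1.0, 3.0], max_dim=1, context=ctx2)
    assert filt.chains[0].dim(0) == 2 and filt.chains[0].dim(1) == 0
    assert filt.chains[1].dim(1) == 1


def test_rips_flag_closure(ctx3):
    """Equilateral side-1 triangle fills its 2-simplex exactly at t=1."""
    tri = PointCloud(
        np.array([[0, 0, 0], [1.0, 0, 0], [0.5, np.sqrt(3) / 2, 0]]), ("C",) * 3
    )
    filt = rips_filtration(tri, grid=[0.99, 1.0], max_dim=2, context=ctx3)
    assert filt.chains[0].dim(2) == 0
    assert filt.chains[1].dim(2) == 1


def test_rips_duplicate_points_enter_at_zero(ctx2):
    cloud = PointCloud(np.array([[0.0, 0, 0], [0.0, 0, 0]]), ("X", "X"))
    filt = rips_filtration(cloud, grid=[0.0, 1.0], max_dim=1, context=ctx2)
    assert filt.chains[0].dim(1) == 1


def test_rips_rejects_nonfinite_coordinates():
    with pytest.raises(ValueError):
        PointCloud(np.array([[np.inf, 0, 0]]), ("X",))


def test_rips_nestedness(random_cloud6, ctx3):
    """Every simplex present at x is present at every y >= x."""
    filt = rips_filtration(random_cloud6, r_max=7.0, steps=28, max_dim=2, context=ctx3)
    for a, b in zip(filt.chains, filt.chains[1:]):
        for n in a.bases:
            assert set(a.bases[n]) <= set(b.bases.get(n, []))


def test_default_grid_spacing(random_cloud6, ctx3):
    filt = rips_filtration(random_cloud6, r_min=0.0, r_max=7.0, steps=28, context=ctx3)
    assert len(filt.grid) == 28
    assert np.allclose(np.diff(filt.grid), 0.25)
    assert np.isclose(filt.grid[-1], 7.0)


def test_element_filter_preserves_order():
    cloud = PointCloud(np.arange(15, dtype=float).reshape(5, 3), ("B", "C", "B", "H", "B"))
    sub = element_filter(cloud, "B")
    assert sub.labels == ("B", "B", "B")
    assert np.allclose(sub.coordinates[:, 0], [0, 6, 12])
    with pytest.warns(UserWarning):
        empty = element_filter(cloud, "Se")
    assert len(empty) == 0


def test_persistent_betti_reduces_at_equal_steps(random_cloud6, ctx3):
    """beta^{x,x}_{n,q} equals the non-persistent Betti at that step."""
    filt = rips_filtration(random_cloud6, grid=[1.0, 2.0, 3.0], max_dim=3, context=ctx3)
    for x in filt.grid:
        chain = filt.chain_at(x)
        for n in (0, 1):
            for q in (1, 2):
                assert persistent_betti(filt, x, x, n, q) == mayer_betti(chain, n, q).betti


def test_two_component_merge_classical(ctx2):
    """N=2 persistent Betti across a merge: the two components become one."""
    filt = rips_filtration(_two_point_cloud(), grid=[1.0, 3.0], max_dim=1, context=ctx2)
    assert persistent_betti(filt, 1.0, 3.0, 0, 1) == 1
    assert persistent_betti_subspace(filt, 1.0, 3.0, 0, 1) == 1


def test_persistent_betti_monotone_bounds(random_cloud6, ctx3):
    """beta^{x,y} <= min(beta(x), beta(y)) and is non-increasing in y."""
    filt = rips_filtration(random_cloud6, grid=[0.8, 1.6, 2.4], max_dim=3, context=ctx3)
    g = filt.grid
    for n in (0, 1):
        for q in (1, 2):
            prev = None
            for yi in range(len(g)):
                b = persistent_betti(filt, g[0], g[yi], n, q)
                bx = mayer_betti(filt.chains[0], n, q).betti
                by = mayer_betti(filt.chains[yi], n, q).betti
                assert b <= min(bx, by)
                if prev is not None:
                    assert b <= prev
                prev = b


def test_laplacian_equals_subspace_oracle(random_cloud6, ctx3):
    """Persistent-Laplacian nullity equals the subspace-intersection count."""
    filt = rips_filtration(random_cloud6, grid=[0.8, 1.6, 2.4, 4.0], max_dim=3, context=ctx3)
    g = filt.grid
    for xi in range(len(g)):
        for yi in range(xi, len(g)):
            for n in (0, 1):
                for q in (1, 2):
                    a = persistent_betti(filt, g[xi], g[yi], n, q)
                    b = persistent_betti_subspace(filt, g[xi], g[yi], n, q)
                    assert a == b, (xi, yi, n, q)


def test_persistent_laplacian_at_equal_steps_is_plain(random_cloud6, ctx3):
    filt = rips_filtration(random_cloud6, grid=[1.5, 2.5], max_dim=3, context=ctx3)
    for x in filt.grid:
        for n in (0, 1):
            for q in (1, 2):
                P = persistent_laplacian(filt, x, x, n, q).matrix
                L = mayer_laplacian(filt.chain_at(x), n, q).total
                assert P.shape == L.shape
                if L.size:
                    assert np.max(np.abs(P - L)) < 1e-10


def test_persistent_laplacian_hermitian_psd_sweep(random_cloud6, ctx3):
    filt = rips_filtration(random_cloud6, grid=[1.0, 2.0, 3.0], max_dim=3, context=ctx3)
    g = filt.grid
    for xi in range(len(g)):
        for yi in range(xi, len(g)):
            for n in (0, 1):
                for q in (1, 2):
                    M = persistent_laplacian(filt, g[xi], g[yi], n, q).matrix
                    if M.size == 0:
                        continue
                    assert np.max(np.abs(M - M.conj().T)) < 1e-10
                    assert np.linalg.eigvalsh(M).min() > -1e-10


def test_persistent_laplacian_below_q_is_up_only(random_cloud6, ctx3):
    """For n < q the Down term vanishes (d^q = 0 below grade q)."""
    filt = rips_filtration(random_cloud6, grid=[1.0, 2.5], max_dim=3, context=ctx3)
    P = persistent_laplacian(filt, 1.0, 2.5, 0, 2)
    A = filt.chain_at(1.0)
    # the Down contribution is exactly zero, so P is PSD with the Up rank
    assert P.matrix.shape == (A.dim(0), A.dim(0))


def test_persistent_dirac_matches_plain_at_equal_steps(random_cloud6, ctx3):
    filt = rips_filtration(random_cloud6, grid=[1.5, 2.5], max_dim=3, context=ctx3)
    for x in filt.grid:
        for (k, i, q) in [(0, 0, 1), (1, 0, 1), (0, 0, 2), (0, 1, 1)]:
            Dp = persistent_dirac(filt, x, x, k, i, q).matrix
            D = dirac_matrix(filt.chain_at(x), k, i, q).matrix
            assert Dp.shape == D.shape
            if D.size:
                assert np.allclose(
                    np.linalg.eigvalsh(Dp), np.linalg.eigvalsh(D), atol=1e-8
                )


def test_persistent_dirac_hermitian_symmetric_spectrum(random_cloud6, ctx3):
    filt = rips_filtration(random_cloud6, grid=[1.0, 2.0, 3.0], max_dim=3, context=ctx3)
    g = filt.grid
    for xi in range(len(g)):
        for yi in range(xi, len(g)):
            D = persistent_dirac(filt, g[xi], g[yi], 0, 0, 1).matrix
            if D.size == 0:
                continue
            assert np.max(np.abs(D - D.conj().T)) < 1e-10
            ev = np.linalg.eigvalsh(D)
            assert np.max(np.abs(np.sort(ev) - np.sort(-ev))) < 1e-8


def test_persistent_dirac_square_block_nullities(ctx3):
    """Nullity of (D^{A,B})^2 equals the sum of its diagonal-block nullities."""
    tri = PointCloud(
        np.array([[0, 0, 0], [1.0, 0, 0], [0.5, np.sqrt(3) / 2, 0]]), ("C",) * 3
    )
    filt = rips_filtration(tri, grid=[0.5, 1.0], max_dim=2, context=ctx3)
    D = persistent_dirac(filt, 0.5, 1.0, 0, 0, 1)
    M2 = D.matrix @ D.matrix
    total = spectrum(M2).nullity
    offs = np.concatenate([[0], np.cumsum(D.block_sizes)])
    parts = 0
    for b in range(len(D.block_sizes)):
        s = slice(int(offs[b]), int(offs[b + 1]))
        parts += spectrum(M2[s, s]).nullity
    assert total == parts


@pytest.mark.parametrize("n", [0, 1])
def test_n2_persistence_matches_classical_oracle(random_cloud6, ctx2, n):
    """N=2 persistent Betti equals an independent classical computation."""
    filt = rips_filtration(random_cloud6, grid=[0.8, 1.6, 2.4, 4.0], max_dim=3, context=ctx2)
    g = filt.grid
    for xi in range(len(g)):
        for yi in range(xi, len(g)):
            A = [s.vertices for b in filt.chains[xi].bases.values() for s in b]
            B = [s.vertices for b in filt.chains[yi].bases.values() for s in b]
            expected = classical_persistent_betti(A, B, n)
            assert persistent_betti(filt, g[xi], g[yi], n, 1) == expected


def test_nullity_curve_is_classical_staircase_at_n2(random_cloud6, ctx2):
    """Single-step Dirac nullity at N=2 decomposes classically per step."""
    filt = rips_filtration(random_cloud6, grid=[1.0, 2.0, 3.0, 4.0], max_dim=2, context=ctx2)
    tab = persistence_curves(filt, ["nullity"], k=0, i=0, q=1)
    for row, chain in zip(tab.itertuples(), filt.chains):
        simp = [s.vertices for b in chain.bases.values() for s in b]
        from _classical import classical_betti, classical_boundary

        beta0 = classical_betti(simp, 0)
        B1 = classical_boundary(simp, 1)
        down_nullity = B1.shape[1] - np.linalg.matrix_rank(B1) if B1.size else chain.dim(1)
        assert row.nullity == beta0 + down_nullity


def test_curves_empty_filtration(ctx3):
    filt = rips_filtration(PointCloud(np.zeros((0, 3)), ()), grid=[1.0, 2.0], context=ctx3)
    tab = persistence_curves(filt, ["nullity"])
    assert tab.empty


def test_curves_unknown_feature_rejected(random_cloud6, ctx3):
    filt = rips_filtration(random_cloud6, grid=[1.0], max_dim=1, context=ctx3)
    with pytest.raises(ValueError, match="known"):
        persistence_curves(filt, ["not_a_feature"])


def test_mayer_curves_separate_what_classical_cannot(ctx2, ctx3):
    """Filled triangle + apex vs two segments: equal N=2 persistent Betti
    curves, different N=3 Mayer Betti curves (higher-order sensitivity)."""
    A = PointCloud(
        np.array([[0, 0, 0], [1.0, 0, 0], [0.5, np.sqrt(3) / 2, 0], [10.0, 0, 0]]),
        ("X",) * 4,
    )
    B = PointCloud(
        np.array([[0, 0, 0], [1.0, 0, 0], [10.0, 0, 0], [11.0, 0, 0]]), ("X",) * 4
    )
    grid = [0.5, 1.0, 1.5]
    # classical persistent Betti in degrees 0 and 1 agree at every pair
    fA2 = rips_filtration(A, grid=grid, max_dim=2, context=ctx2)
    fB2 = rips_filtration(B, grid=grid, max_dim=2, context=ctx2)
    for xi in range(3):
        for yi in range(xi, 3):
            for n in (0, 1):
                assert persistent_betti(fA2, grid[xi], grid[yi], n, 1) == persistent_betti(
                    fB2, grid[xi], grid[yi], n, 1
                )
    # the Mayer N=3 Betti curves differ
    fA3 = rips_filtration(A, grid=grid, max_dim=2, context=ctx3)
    fB3 = rips_filtration(B, grid=grid, max_dim=2, context=ctx3)
    diffs = [
        mayer_betti(fA3.chain_at(t), n, q).betti != mayer_betti(fB3.chain_at(t), n, q).betti
        for t in grid
        for n in (0, 1)
        for q in (1, 2)
    ]
    assert any(diffs)


def test_betti_curves_invariant_under_point_relabeling(ctx3):
    """Mayer Betti numbers do not depend on the vertex input order."""
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 2.5, (6, 3))
    base = PointCloud(pts, ("X",) * 6)
    f0 = rips_filtration(base, grid=[1.2, 2.0, 3.0], max_dim=2, context=ctx3)
    for seed in (1, 2):
        perm = np.random.default_rng(seed).permutation(6)
        f1 = rips_filtration(
            PointCloud(pts[perm], ("X",) * 6), grid=[1.2, 2.0, 3.0], max_dim=2, context=ctx3
        )
        for c0, c1 in zip(f0.chains, f1.chains):
            from mayerdirac import betti_table

            assert betti_table(c0) == betti_table(c1)
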