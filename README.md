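# mayerdirac

Mayer N-chain complexes, Mayer Laplacian/Dirac operators, and persistent
spectral fingerprints for molecular point clouds.

## The problem

Classical persistent homology looks at a molecule's atoms through the
boundary operator of a simplicial complex, for which `d² = 0`.  A *Mayer*
N-chain complex relaxes this to `d^N = 0`: the boundary of an ordered
vertex tuple is weighted by powers of a primitive N-th root of unity
ξ = e^{2πi/N},

    d (v₀, …, vₙ) = Σᵢ ξ^i (v₀, …, v̂ᵢ, …, vₙ),

so that only the N-fold composition vanishes.  For each 1 ≤ q ≤ N−1 this
yields Mayer homology groups H_{n,q} = ker d^q / im d^{N−q} whose
dimensions β_{n,q} (computed here as
`dim Cₙ − rank d_n^q − rank d_{n+N−q}^{N−q}`) see structure that classical
Betti numbers cannot — for example, each standard simplex σ[0]…σ[6]
carries its own distinctive table of nonzero β_{n,q}.  On top of the chain
complex the package builds the full operator stack:

* **Mayer Laplacians** `L_{n,q} = B_{n+N−q,N−q} B^H + B_{n,q}^H B_{n,q}`,
  Hermitian PSD with `nullity(L_{n,q}) = β_{n,q}`;
* **Mayer Dirac operators** `D_{k,i,q}`, Hermitian block-tridiagonal
  matrices over the alternating q-/(N−q)-step 2-chain families, with
  symmetric spectra and `D²` block diagonal in Mayer Laplacians;
* the **factorization operators** `X_{k,q}` with `X^H X` reproducing the
  Laplacian blocks;
* **persistent** versions of all of the above over Vietoris–Rips
  filtrations of labeled point clouds (atoms as points, element-specific
  selections), including the persistent Mayer Laplacian built from the
  preimage subspace `{x ∈ B_{n+N−q} : b^{N−q}x ∈ A_n}`;
* **spectral descriptors** (Dirac zeta values, complexities, Euler pairs,
  spanning-tree number, means, graph energy, quasi-Wiener index) that turn
  the spectra into fingerprint curves for comparing molecules — e.g.
  isomers with identical composition but different geometry.

It is aimed at researchers in topological data analysis and
cheminformatics who want higher-order (N > 2) spectral invariants of
molecular or other low-dimensional point-cloud data.

## Worked example

The 3-chain of the full triangle (vertices 0, 1, 2 and all faces):

```python
import numpy as np
import mayerdirac as md
from mayerdirac.homology import format_betti_table

ctx = md.make_context(3)                     # N = 3, xi = e^{2*pi*i/3}
chain = md.build_simplicial_nchain(md.standard_simplex_complex(2), ctx)

print(format_betti_table(md.betti_table(chain)))
# beta_{0,1} = 2, beta_{1,2} = 2

spec = md.spectrum(md.dirac_matrix(chain, 0, 0, 1).matrix)
print(np.round(spec.eigenvalues, 4), spec.nullity)
# [-1.8794 -1.5321 -0.3473  0.3473  1.5321  1.8794] 0

feats = md.spectral_features(spec.eigenvalues, dimension=6)
print(round(feats.zeta_m1, 4), feats.euler_pairs, round(feats.spanning_tree, 4))
# 3.7588 3.0 -1.3863
```

The Betti line says the triangle's Mayer 3-chain has two-dimensional
homology exactly at (n, q) = (0, 1) and (1, 2) — unlike its classical
homology, which is ℂ in degree 0 only.  The Dirac operator `D_{0,0,1}`
(acting on C₀ ⊕ C₁) has a symmetric spectrum with no kernel; its positive
eigenvalues give a graph energy ξ(−1) ≈ 3.76, l(D) = 3 nonzero eigenvalue
pairs, and spanning-tree number t(D) ≈ −1.386.

Molecular fingerprints compare two synthetic B₇C₂H₉-like isomer cages
through element-specific filtration of their boron atoms:

```python
iso1, iso2 = md.synth_isomer_pair(7)
cfg = md.FingerprintConfig(N=3, q_list=(1, 2), ki_list=((0, 0), (1, 0)),
                           element="B", features=("nullity",))
f1, f2 = md.fingerprint(iso1.points, cfg), md.fingerprint(iso2.points, cfg)
d = abs(f1.to_numpy()[:, 1:] - f2.to_numpy()[:, 1:])
print(d.sum(), d.max())   # 74.0 13.0
```

The same comparison at N = 2 gives a total separation of 46 — the Mayer
structure widens the gap between isomers because it distinguishes
simplices of different dimensions.

A `mayer-dirac` command-line tool exposes the same functionality
(`betti`, `spectrum`, `dirac`, `fingerprint`, `persist`, `synth`); see
`mayer-dirac --help`.

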