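# Methods

## The Mayer N-chain model

An N-chain complex is a graded complex vector space C₀, C₁, … with linear
boundary maps dₙ : Cₙ → Cₙ₋₁ such that any N consecutive maps compose to
zero.  The package realizes the root-of-unity construction: fixing the
primitive N-th root ξ = e^{2πi/N}, the boundary of an ordered tuple
removes each entry with coefficient ξ^i.  The identity
Σ_{i=0}^{N−1} ξ^i = 0 forces d^N = 0, while partial sums
S(k) = 1 + ξ + … + ξ^{k−1} stay nonzero for k < N, so lower powers of d
are genuinely nonzero.  The q-fold composition has the closed form

    B_{n,q}(τ, σ) = (w_τ / w_σ) · α_q · Σ_{σ^j = τ} ξ^{[j]},
    α_q = ξ^{−q(q−1)/2} · Π_{k=1}^{q} S(k),

where j ranges over increasing q-tuples of removal positions and
[j] = j₁ + … + j_q.  Both routes — the matrix product
B_{n−q+1}⋯B_n and the entrywise formula — are implemented and tested
against each other.

Two complexes are built.  The *simplicial* N-subchain is spanned by the
strictly increasing vertex tuples of a simplicial complex; this is the
default for every application.  The *full tuple* complex on V^{n+1}
(repeats allowed) is a verification device only: it grows as |V|^{n+1}
and sits behind a basis-size cap (20 000 elements per grade).

For each 1 ≤ q ≤ N−1, Mayer homology is
H_{n,q} = ker d^q / im d^{N−q}, and its dimension is computed from ranks:
β_{n,q} = dim Cₙ − rank(dₙ^q) − rank(d_{n+N−q}^{N−q}).  Grades outside
the built complex are zero spaces; this convention is forced by the
definitions and makes the boundary cases (a single point, small
simplices) come out right.  Note that for a built complex of top
dimension T the formula can be nonzero for n up to T, including cells a
casual tabulation might miss: for the standard 4-simplex at N = 5 the
formula yields β_{1,3} = 5 by exactly the same computation that gives
β_{1,3} = 5 for the 3-simplex.  The package always reports what the
formula yields; the exact-arithmetic oracle (below) certifies those
values independently of floating point.

## Weights

The inner product is ⟨λσ, µτ⟩ = λ·conj(µ)·w_σ² δ_{στ} with w_σ > 0; all
matrices are stored on the orthonormal basis {σ/w_σ}.  Three schemes are
provided: unit weights; an explicit per-simplex table; and the
geometry-derived scheme w_σ = mean pairwise Euclidean distance of the
simplex's vertices (vertices get w = 1).  The weighting recipe used for
molecular applications is stated in terms of the *squared* average
distance, which is ambiguous between "w_σ equals the squared mean" and
"w_σ² equals the squared mean (so w_σ is the mean)".  The default is
w_σ = mean distance — then the inner-product factor w_σ² is the squared
mean — and the squared reading is available via
`WeightScheme.mean_distance(coords, squared=True)`.  Coincident points
would give w = 0, so degenerate simplices fall back to unit weight to
keep the inner product positive definite.

## Operators

* **Laplacian.**  L_{n,q} = B_{n+N−q,N−q} B^H + B_{n,q}^H B_{n,q};
  Hermitian PSD, kernel dimension β_{n,q}.  An independent entrywise
  assembly (sums over shared faces/cofaces weighted by
  w²|α|²-factors and ξ^{[j]−[s]} phases) is restricted to simplicial
  chains, where the removal-position tuple per face pair is unique.
* **Omega families.**  For 0 ≤ i < N−q the grades i, i+q, i+N, i+N+q, …
  with alternating q-step and (N−q)-step boundaries form an ordinary
  2-chain complex; every Mayer homology group of the parent appears at
  exactly one (j, i, q).
* **Dirac.**  D_{k,i,q} is the Hermitian block-tridiagonal matrix of the
  first k+2 grades of that family.  Its square is block diagonal: full
  Mayer Laplacians on blocks 0..k and the Down term on block k+1.  The
  identity is asserted entrywise (tolerance 1e−10) on the truncated
  assembly, with unbuilt grades as zero spaces.
* **Factorization.**  X_{k,q} places B_{j,q} on the q-th block
  superdiagonal and adjoints of (N−q)-step boundaries on the (N−q)-th
  block subdiagonal, over grades 0..k+N−q.  One correction to the usual
  statement of the adjoint identity: the adjoint of X_{k,q} is the X
  operator with parameter N−q *on the same grade span*, i.e.
  X_{k+N−2q, N−q} in this k-indexing — the spans of X_{k,q} and
  X_{k,N−q} differ unless q = N/2, so the unqualified identity cannot
  typecheck.  `x_factor` therefore accepts an explicit top grade.  X is
  non-Hermitian in general (Hermitian exactly when N is even and
  q = N/2, recovering the classical Dirac at N = 2) and is analyzed
  through singular values, never through the Hermitian eigensolver.

## Persistence

Point clouds filter through Vietoris–Rips flag complexes: a simplex is
present at scale t when all pairwise distances within it are ≤ t (it
enters at its diameter).  The default grid is 28 uniform values on
(0, 7] Å (0.25 Å spacing), configurable; element-specific filtration
restricts the cloud to one atom type first.  Flag complexes are
enumerated from the threshold graph's cliques, which is adequate at the
desk scales this package targets (tens of points).

For a pair of steps x ≤ y with complexes A ⊆ B:

* the **persistent Betti number** is the rank of the inclusion-induced
  map on Mayer homology;
* the **persistent Laplacian** on A_n adds A's own q-step Down term to an
  Up term obtained by compressing B's (N−q)-step boundary to an
  orthonormal basis of the preimage subspace
  {v ∈ B_{n+N−q} : b^{N−q}v ∈ A_n} (computed as the null space of the
  boundary rows outside A_n); its nullity equals the persistent Betti
  number, which is also computed by an independent subspace route
  dim Z(A) − dim(Z(A) ∩ im b^{N−q}(B)) and cross-checked;
* the **persistent Dirac** is the Dirac operator of the auxiliary
  complex C₀ = B_i, Cₘ = preimage of A's grade t_{m−1} under B's
  alternating step maps, each grade realized as an orthonormal subspace
  basis with the maps compressed accordingly.  At x = y the subspaces
  are full and the operator is unitarily equivalent to the
  non-persistent Dirac (equal spectra; the matrix itself depends on the
  basis choice, but every reported quantity is basis-invariant).

## Spectral descriptors and fingerprints

All descriptors are functions of the positive eigenvalues λ₁..λ_k of a
Hermitian operator: ξ_D(s) = Σ λᵢ^{−s} (energy ξ(−1), second moment
ξ(−2), quasi-Wiener (k+1)ξ(1)), complexity c_m = (−1)^{km} Π λⱼ^{2m}
kept as (sign, natural-log magnitude) to avoid overflow, Euler pairs
l(D) = (dim − nullity)/2, spanning-tree number
t(D) = ½log|c₁| − log(l+1) evaluated in log space, mean, mean absolute
deviation, extremes, and standard deviation of the positive spectrum.
Conventions for the empty spectrum — ξ = 0, c_m = (+1, 0), mean-type
statistics absent — are explicit and tested.  The positive cutoff is the
same threshold used for nullity and rank decisions everywhere
(max(dim·ε·max|λ|, 1e−10)), so β_{n,q} = nullity(L_{n,q}) cannot drift
from tolerance mismatches.

A fingerprint evaluates a chosen family of (persistent) Mayer Dirac
operators D_{k,i,q} at every grid scale of an element-specific Rips
filtration and tabulates the descriptors: one row per scale, one column
per (operator, feature).  Flattened row vectors use the column naming
`N{N}_q{q}_k{k}i{i}_r{r}_{feature}` so batches of structures stack into
sample-by-feature matrices; a 2-D embedding hook (PCA or t-SNE) is
provided for visualization only.

**Ordering caveat.**  The vertex total order (atom input order) is part
of the construction: for N > 2 the ξ^i coefficients are not intertwined
unitarily by relabelings, so Laplacian/Dirac *eigenvalues* can change
under point reordering on partially built complexes.  Betti numbers and
nullities are order-invariant (asserted by permutation tests), and at
N = 2 the whole spectrum is.  Fingerprints that must be order-robust
should use nullity-derived features or fix a canonical atom order.

## Numerical choices

Complex double precision throughout the main path; Hermitian matrices
are symmetrized before `eigvalsh`.  Rank = number of singular values
above max(m,n)·ε·σ_max with an absolute floor of 1e−10; the same policy
object drives nullity and subspace extraction.  An exact rank oracle
over the cyclotomic field Q(ξ) (prime N, unit or rational weights)
certifies ranks independently of floating point: entries are reduced to
the power basis 1, ξ, …, ξ^{N−2} modulo 1 + x + … + x^{N−1}, the matrix
is blown up by restriction of scalars to a rational matrix, and its
fraction-free rank divided by N−1 is the rank over Q(ξ).  Basis order is
lexicographic by vertex tuple within each dimension, fixing matrix
layouts bit-reproducibly.

## Synthetic fixtures: what they emulate and what they do not

The application datasets behind the fingerprint methodology (carborane
isomer coordinates; the 900-sample halide perovskite set) are not
publicly deposited, so the generators produce synthetic stand-ins:

* `synth_isomer_pair` builds two B₇C₂H₉-composition clouds whose boron
  cages differ (pentagonal bipyramid vs capped stacked triangles) at
  bond-realistic ~1.8 Å B–B distances, with a small seeded jitter.  They
  reproduce the *phenomenon* — element counts match, fingerprints differ,
  and the separation between the pair grows from N = 2 to N = 3 (total
  nullity-curve separation 46 → 74 under the default 0–7 Å, 28-step
  conditions) — not the published curves.
* `synth_perovskite_like` builds one ABX₃-like unit cell with
  halide-scaled lattice constants (Cl < Br < I) and phase-dependent
  axial distortions plus seeded thermal jitter.  It exercises the
  fingerprint pipeline shape and determinism, not the published
  clustering.

Passing tests on these fixtures therefore demonstrate correctness of the
operators and the direction of the isomer-separation effect on
constructed geometry; they say nothing quantitative about real
carboranes or perovskites.

## Problem sizes

The shipped computations are desk-scale by design: standard simplices up
to σ[6] (largest boundary matrix 35 columns), random flag complexes on
≤ 6 points, filtrations of ≤ 8-point clouds on short grids, and the
7-boron isomer sub-clouds on the full 28-step grid.  The whole test
suite runs in a few seconds; the exact cyclotomic oracle is reserved for
small certification fixtures since restriction of scalars multiplies
matrix sizes by N−1.

## Known limitations

* Coefficients are complex only; the finite-field variant of Mayer
  complexes is out of scope.
* The exact oracle requires prime N and exact (unit/rational) weights.
* Dense linear algebra only; no sparse or iterative eigensolvers.
* Rips flag complexes are enumerated exhaustively — fine for tens of
  points, not for thousands.
* No persistence diagrams/barcodes in the pairing sense: persistent
  Betti numbers and spectra only.
* No bond perception, charges, or force fields; structures are point
  clouds with element labels.
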