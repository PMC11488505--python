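"""Spectral descriptors of Hermitian operators.

All descriptors are functions of the positive eigenvalues lambda_1..lambda_k
of a Hermitian operator D on a dim(V)-dimensional space:

* Dirac zeta            xi_D(s) = sum_i lambda_i^{-s}
* m-th complexity       c_m(D) = (-1)^{km} prod_j lambda_j^{2m}
* signless Euler pairs  l(D) = dim(V)/2 - nullity(D)/2
* spanning-tree number  t(D) = log|c_1(D)| / 2 - log(l(D) + 1)
* mean / generalized mean, extremes, standard deviation
* graph energy xi(-1), spectral second moment xi(-2), and the
  quasi-Wiener index (k+1) xi(1)

Complexities are kept in (sign, log-magnitude) form so that large spectra
cannot overflow; logarithms are natural throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tolerances import DEFAULT_TOL, TolerancePolicy

__all__ = [
    "SpectralFeatures",
    "dirac_zeta",
    "complexity",
    "euler_pairs",
    "spanning_tree_number",
    "eigen_stats",
    "spectral_features",
    "FEATURE_NAMES",
    "feature_vector",
    "FingerprintConfig",
    "fingerprint",
    "fingerprint_vector",
    "embed_fingerprints",
]


def _check_positive(eigs: np.ndarray) -> np.ndarray:
    eigs = np.asarray(eigs, dtype=float)
    if eigs.size and np.min(eigs) <= 0:
        raise ValueError("all eigenvalues passed to a descriptor must be positive")
    return eigs


def dirac_zeta(positive_eigs: Sequence[float], s: float) -> float:
    """xi_D(s) = sum lambda_i^{-s}; the empty spectrum gives 0."""
    eigs = _check_positive(np.asarray(positive_eigs))
    if eigs.size == 0:
        return 0.0
    return float(np.sum(eigs ** (-s)))


def complexity(positive_eigs: Sequence[float], m: int) -> tuple[int, float]:
    """c_m(D) as (sign, natural-log magnitude); empty spectrum -> (+1, 0)."""
    if m < 1:
        raise ValueError(f"m must be a positive integer, got {m}")
    eigs = _check_positive(np.asarray(positive_eigs))
    k = eigs.size
    sign = -1 if (k * m) % 2 else 1
    log_mag = float(2 * m * np.sum(np.log(eigs))) if k else 0.0
    return sign, log_mag


def euler_pairs(dimension: int, nullity: int) -> float:
    """l(D) = (dim V - nullity)/2, the number of nonzero eigen pairs."""
    if nullity < 0 or nullity > dimension:
        raise ValueError(f"need 0 <= nullity <= dimension, got {nullity} > {dimension}")
    return (dimension - nullity) / 2


def spanning_tree_number(positive_eigs: Sequence[float], dimension: int) -> float:
    """t(D) = log|c_1|/2 - log(l(D)+1), evaluated in log space.

    The nullity is inferred from the symmetric-spectrum relation
    ``nullity = dim - 2k`` (Dirac spectra come in +/- pairs), so
    l(D) = k.  The empty spectrum uses the empty-product convention
    log|c_1| = 0.
    """
    eigs = _check_positive(np.asarray(positive_eigs))
    k = eigs.size
    if 2 * k > dimension:
        raise ValueError("more positive eigenvalues than dimension/2")
    _, log_c1 = complexity(eigs, 1) if k else (1, 0.0)
    ell = euler_pairs(dimension, dimension - 2 * k)
    return 0.5 * log_c1 - math.log(ell + 1)


def eigen_stats(positive_eigs: Sequence[float]) -> dict[str, float | None]:
    """Mean-type statistics of the positive spectrum.

    Empty spectra yield an all-``None`` record for the mean-type entries
    and 0 for the zeta-derived sums.
    """
    eigs = _check_positive(np.asarray(positive_eigs))
    k = eigs.size
    energy = dirac_zeta(eigs, -1)
    second_moment = dirac_zeta(eigs, -2)
    quasi_wiener = (k + 1) * dirac_zeta(eigs, 1)
    if k == 0:
        return {
            "mean": None,
            "generalized_mean": None,
            "min": None,
            "max": None,
            "std": None,
            "energy": energy,
            "second_moment": second_moment,
            "quasi_wiener": quasi_wiener,
        }
    mean = energy / k
    return {
        "mean": mean,
        "generalized_mean": float(np.sum(np.abs(mean - eigs))) / k,
        "min": float(np.min(eigs)),
        "max": float(np.max(eigs)),
        "std": float(np.std(eigs)),
        "energy": energy,
        "second_moment": second_moment,
        "quasi_wiener": quasi_wiener,
    }


@dataclass(frozen=True)
class SpectralFeatures:
    """Full descriptor record of one Hermitian operator's spectrum."""

    dimension: int
    nullity: int
    k: int
    zeta_m1: float  # xi(-1), graph energy
    zeta_m2: float  # xi(-2), spectral second moment
    zeta_1: float
    zeta_2: float
    quasi_wiener: float
    c1_sign: int
    c1_log_magnitude: float
    euler_pairs: float
    spanning_tree: float
    mean: float | None
    generalized_mean: float | None
    min_pos: float | None
    max_pos: float | None
    std_pos: float | None


def spectral_features(
    eigenvalues: Sequence[float],
    dimension: int | None = None,
    tol: TolerancePolicy = DEFAULT_TOL,
) -> SpectralFeatures:
    """Descriptor record from a full real spectrum.

    The positive part is cut at the shared nullity threshold; ``dimension``
    defaults to the spectrum length.
    """
    eigs = np.sort(np.asarray(eigenvalues, dtype=float))
    dim = len(eigs) if dimension is None else dimension
    lam_max = float(np.max(np.abs(eigs))) if eigs.size else 0.0
    thr = tol.null_threshold(dim, lam_max)
    pos = eigs[eigs > thr]
    nullity = int(np.sum(np.abs(eigs) <= thr))
    k = int(pos.size)
    stats = eigen_stats(pos)
    sign, logmag = complexity(pos, 1) if k else (1, 0.0)
    return SpectralFeatures(
        dimension=dim,
        nullity=nullity,
        k=k,
        zeta_m1=dirac_zeta(pos, -1),
        zeta_m2=dirac_zeta(pos, -2),
        zeta_1=dirac_zeta(pos, 1),
        zeta_2=dirac_zeta(pos, 2),
        quasi_wiener=stats["quasi_wiener"],
        c1_sign=sign,
        c1_log_magnitude=logmag,
        euler_pairs=euler_pairs(dim, nullity),
        spanning_tree=spanning_tree_number(pos, dim) if 2 * k <= dim else float("nan"),
        mean=stats["mean"],
        generalized_mean=stats["generalized_mean"],
        min_pos=stats["min"],
        max_pos=stats["max"],
        std_pos=stats["std"],
    )


#: fixed column order for fingerprint matrices
FEATURE_NAMES: tuple[str, ...] = (
    "nullity",
    "euler_pairs",
    "spanning_tree",
    "mean",
    "generalized_mean",
    "min_pos",
    "max_pos",
    "std_pos",
    "energy",
    "second_moment",
    "zeta_2",
    "quasi_wiener",
)


def feature_vector(feats: SpectralFeatures, names: Sequence[str] = FEATURE_NAMES) -> list[float]:
    """Flatten a record to the named columns (absent stats become 0.0)."""
    lookup = {
        "nullity": float(feats.nullity),
        "euler_pairs": feats.euler_pairs,
        "spanning_tree": feats.spanning_tree,
        "mean": feats.mean,
        "generalized_mean": feats.generalized_mean,
        "min_pos": feats.min_pos,
        "max_pos": feats.max_pos,
        "std_pos": feats.std_pos,
        "energy": feats.zeta_m1,
        "second_moment": feats.zeta_m2,
        "zeta_2": feats.zeta_2,
        "quasi_wiener": feats.quasi_wiener,
        "c1_sign": float(feats.c1_sign),
        "c1_log_magnitude": feats.c1_log_magnitude,
    }
    out = []
    for name in names:
        if name not in lookup:
            raise KeyError(
                f"unknown feature {name!r}; known features: {sorted(lookup)}"
            )
        v = lookup[name]
        out.append(0.0 if v is None else float(v))
    return out


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FingerprintConfig:
    """What to compute for a molecular fingerprint.

    ``q_list`` and ``ki_list`` select the (persistent) Mayer Dirac
    operators D_{k,i,q}; one curve of features is produced per operator
    per grid value.  ``element`` restricts the cloud to one atom type
    (element-specific filtration); ``None`` keeps all atoms.
    """

    N: int = 3
    q_list: tuple[int, ...] = (1,)
    ki_list: tuple[tuple[int, int], ...] = ((0, 0),)
    r_min: float = 0.0
    r_max: float = 7.0
    steps: int = 28
    weights: str = "unit"
    element: str | None = None
    mode: str = "single"
    features: tuple[str, ...] = FEATURE_NAMES
    max_dim: int | None = None


def _required_max_dim(cfg: FingerprintConfig) -> int:
    # highest chain grade touched by any requested Dirac is t_{k+1}
    top = 0
    for q in cfg.q_list:
        for k, i in cfg.ki_list:
            j = k + 1
            t = i + ((j - 1) // 2) * cfg.N + q if j % 2 else i + (j // 2) * cfg.N
            top = max(top, t)
    return top


def fingerprint(cloud, config: FingerprintConfig = FingerprintConfig(), tol=DEFAULT_TOL):
    """Feature table of (persistent) Mayer Dirac spectra over the grid.

    Returns a DataFrame with one row per grid value and one column per
    (operator index, feature); an empty point cloud yields an empty table
    with the header in place.
    """
    import pandas as pd

    from .chain_complex import make_context
    from .persistence import element_filter, persistence_curves, rips_filtration

    if config.element is not None:
        cloud = element_filter(cloud, config.element)
    columns: list[str] = []
    per_op: list = []
    context = make_context(config.N)
    max_dim = config.max_dim if config.max_dim is not None else _required_max_dim(config)
    filt = rips_filtration(
        cloud,
        r_min=config.r_min,
        r_max=config.r_max,
        steps=config.steps,
        max_dim=max_dim,
        context=context,
        weights=config.weights,
    )
    for q in config.q_list:
        for k, i in config.ki_list:
            if not 0 <= i < config.N - q:
                raise ValueError(f"(k={k}, i={i}, q={q}) violates 0 <= i < N-q")
            tab = persistence_curves(
                filt, config.features, k=k, i=i, q=q, mode=config.mode, tol=tol
            )
            prefix = f"N{config.N}_q{q}_k{k}i{i}"
            for f in config.features:
                columns.append(f"{prefix}_{f}")
            if tab.empty:
                per_op.append(np.zeros((0, len(config.features))))
            else:
                per_op.append(tab[list(config.features)].to_numpy())
    if not per_op or all(block.shape[0] == 0 for block in per_op):
        return pd.DataFrame(columns=["r", *columns])
    nrows = per_op[0].shape[0]
    data = np.hstack(per_op)
    grid = filt.grid[:nrows]
    out = pd.DataFrame(data, columns=columns)
    out.insert(0, "r", grid)
    return out


def fingerprint_vector(cloud, config: FingerprintConfig = FingerprintConfig(), tol=DEFAULT_TOL):
    """Flatten the fingerprint table to one named row vector.

    Column names follow ``N{N}_q{q}_k{k}i{i}_r{grid}_{feature}`` so a batch
    of structures can be stacked into a sample-by-feature matrix.
    """
    import pandas as pd

    tab = fingerprint(cloud, config, tol)
    names, vals = [], []
    for _, row in tab.iterrows():
        r = row["r"]
        for col in tab.columns:
            if col == "r":
                continue
            pN, pq, pki, feat = col.split("_", 3)
            names.append(f"{pN}_{pq}_{pki}_r{r:g}_{feat}")
            vals.append(float(row[col]))
    return pd.Series(vals, index=names)


def embed_fingerprints(matrix, method: str = "pca", random_state: int = 0):
    """2-D embedding hook for fingerprint matrices (visualization plumbing)."""
    X = np.asarray(matrix, dtype=float)
    if method == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=2, random_state=random_state).fit_transform(X)
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = max(2.0, min(30.0, (X.shape[0] - 1) / 3))
        return TSNE(
            n_components=2, random_state=random_state, init="pca", perplexity=perplexity
        ).fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r}")
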