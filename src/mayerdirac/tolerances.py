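"""Shared numerical tolerance policy.

Rank decisions (singular values) and nullity decisions (eigenvalues) must
agree, otherwise the identity ``beta_{n,q} = nullity(L_{n,q})`` can drift
apart purely from threshold mismatches.  Every module therefore funnels
through one :class:`TolerancePolicy` instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TolerancePolicy", "DEFAULT_TOL"]


@dataclass(frozen=True)
class TolerancePolicy:
    """Relative threshold with an absolute floor.

    A singular value s of an (m, n) matrix counts toward the rank when
    ``s > max(m, n) * eps * s_max`` with an absolute floor of ``floor``.
    An eigenvalue lambda of a d-dimensional Hermitian operator counts as
    zero when ``|lambda| <= max(d * eps * max|lambda|, floor)``.
    """

    floor: float = 1e-10
    eps: float = float(np.finfo(np.float64).eps)

    def rank_threshold(self, shape: tuple[int, int], smax: float) -> float:
        if not shape or min(shape) == 0:
            return self.floor
        return max(max(shape) * self.eps * smax, self.floor)

    def null_threshold(self, dim: int, lam_max: float) -> float:
        return max(dim * self.eps * lam_max, self.floor)

    def is_zero_eig(self, lam: float, dim: int, lam_max: float) -> bool:
        return abs(lam) <= self.null_threshold(dim, lam_max)


DEFAULT_TOL = TolerancePolicy()
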