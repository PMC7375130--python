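"""Maximum-likelihood intrinsic dimensionality estimation.

The Levina-Bickel estimator treats the number of neighbors within a
growing distance ball as a Poisson process; inverting the resulting
likelihood gives, for each point x and neighbor count k,

    m_k(x) = [ (1/(k-1)) * sum_{j<k} log( T_k(x) / T_j(x) ) ]^{-1}

with T_j(x) the Euclidean distance to the j-th nearest neighbor.  The
estimate is averaged over points for each k and then over a k range,
conventionally k = 10..20.  Because only distance ratios enter, the
estimate is invariant to rotation, translation and positive rescaling of
the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["DimensionEstimate", "estimate_intrinsic_dimension"]


@dataclass
class DimensionEstimate:
    estimate: float
    per_k: dict[int, float]
    k_range: tuple[int, int]
    n_points: int
    inverse_averaged: bool = False

    def to_dict(self) -> dict:
        return {
            "estimate": float(self.estimate),
            "per_k": {int(k): float(v) for k, v in self.per_k.items()},
            "k1": self.k_range[0],
            "k2": self.k_range[1],
            "n_points": self.n_points,
            "inverse_averaged": self.inverse_averaged,
        }


def estimate_intrinsic_dimension(X: np.ndarray, k1: int = 10, k2: int = 20,
                                 average_inverses: bool = False
                                 ) -> DimensionEstimate:
    """Levina-Bickel ML intrinsic dimension of an n x m point cloud.

    ``average_inverses`` switches to the bias-corrected variant that
    averages 1/m_k over points before inverting (MacKay-Ghahramani); the
    default averages m_k directly, per the original scheme.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= k1 <= k2:
        raise ValueError("need 2 <= k1 <= k2")
    if k2 >= n:
        raise ValueError("k2 must be below the number of points")
    nn = NearestNeighbors(n_neighbors=k2 + 1, algorithm="brute").fit(X)
    dist, _ = nn.kneighbors(X)
    T = dist[:, 1:]                    # drop self-distance
    if np.any(T[:, 0] == 0):
        raise ValueError("duplicate points give zero nearest-neighbor "
                         "distances")
    logT = np.log(T)
    per_k = {}
    for k in range(k1, k2 + 1):
        # mean over j < k of log(T_k / T_j)
        mk_inv = logT[:, k - 1][:, None] - logT[:, : k - 1]
        mk_inv = mk_inv.mean(axis=1)
        if average_inverses:
            per_k[k] = float(1.0 / mk_inv.mean())
        else:
            per_k[k] = float(np.mean(1.0 / mk_inv))
    est = float(np.mean(list(per_k.values())))
    return DimensionEstimate(estimate=est, per_k=per_k, k_range=(k1, k2),
                             n_points=n, inverse_averaged=average_inverses)
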