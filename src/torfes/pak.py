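"""Point-adaptive local density estimation (PAk-style).

For each sampled configuration, the neighbourhood size ``k`` is grown
until a likelihood-ratio test detects that the density of the point and
of its (k+1)-th neighbour can no longer be considered equal.  The local
density is then ``k / (N * V_k)``, with ``V_k`` the hypersphere volume
out to the k-th neighbour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import ConfigurationSet, NeighborTable, hypersphere_volume, nearest_neighbors

__all__ = [
    "DensityEstimate",
    "DEFAULT_D_THR",
    "log_likelihood",
    "model_likelihoods",
    "likelihood_ratio_Dk",
    "select_k",
    "estimate_densities",
]

#: Likelihood-ratio threshold at which two neighbourhood densities are
#: declared different.
DEFAULT_D_THR: float = 23.928

DEFAULT_K_MIN: int = 4
DEFAULT_K_MAX: int = 256


@dataclass
class DensityEstimate:
    """Per-point density estimate (biased, probability-normalized).

    Attributes
    ----------
    rho : (N,) array
        Estimated density in rad^-D, positive.
    k_selected : (N,) int array
        Neighbourhood size chosen per point.
    V_k : (N,) array
        Hypersphere volume out to the selected neighbour.
    """

    rho: np.ndarray
    k_selected: np.ndarray
    V_k: np.ndarray

    @property
    def n(self) -> int:
        return self.rho.shape[0]


def log_likelihood(rho: float, k: int, v_k: float) -> float:
    """Log-likelihood of density ``rho`` given ``k`` neighbours in volume ``v_k``."""
    if rho <= 0 or v_k <= 0:
        raise ValueError("rho and V_k must be positive")
    return k * math.log(rho) - rho * v_k

def model_likelihoods(k: int, v_k: float, v_j: float) -> tuple[float, float]:
    """Maximized log-likelihoods of the independent / identical density models.

    Model 1 treats the densities of the point and of its (k+1)-th
    neighbour as independent, model 2 as identical.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if v_k <= 0 or v_j <= 0:
        raise ValueError("volumes must be positive")
    l_m1 = k * math.log(k * k / (v_k * v_j)) - 2.0 * k
    l_m2 = 2.0 * k * math.log(2.0 * k / (v_k + v_j)) - 2.0 * k
    return l_m1, l_m2


def likelihood_ratio_Dk(k: int, v_k: float, v_j: float) -> float:
    """Likelihood-ratio statistic ``-2 (L_M2 - L_M1) >= 0``."""
    l_m1, l_m2 = model_likelihoods(k, v_k, v_j)
    return -2.0 * (l_m2 - l_m1)


def _cumulative_volumes(neighbors: NeighborTable, d: int) -> np.ndarray:
    """Hypersphere volumes to each neighbour, shape (N, k_max)."""
    return hypersphere_volume(d, neighbors.distances)


def _dk_matrix(
    volumes: np.ndarray, indices: np.ndarray, k_min: int, rows: np.ndarray = None
) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-ratio statistics for all candidate k, vectorized.

    Returns ``(ks, Dk)`` where ``ks = [k_min, ..., k_max - 1]`` and
    ``Dk[i, c]`` is the statistic for point i at ``k = ks[c]``.  The two
    compared k-neighbour volumes are ``V_k`` around point i and ``V_j``
    around j, the (k+1)-th neighbour of i — i.e. two *different* points'
    candidate densities, tested for equality.  Zero volumes (exact
    duplicate stacks) yield a statistic of 0 so the scan continues.
    """
    k_max = volumes.shape[1]
    if rows is None:
        rows = np.arange(volumes.shape[0])
    ks = np.arange(k_min, k_max)
    v_k = volumes[rows][:, ks - 1]
    # j = (k+1)-th neighbour of i lives at column k (0-based); its own
    # k-neighbour volume sits in its row at column k-1
    v_j = volumes[indices[rows][:, ks], ks[None, :] - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        l_m1 = ks * np.log(ks**2 / (v_k * v_j)) - 2.0 * ks
        l_m2 = 2.0 * ks * np.log(2.0 * ks / (v_k + v_j)) - 2.0 * ks
        dk = -2.0 * (l_m2 - l_m1)
    dk = np.where((v_k == 0) | (v_j == 0), 0.0, dk)
    return ks, dk


def select_k(
    point_index: int,
    neighbors: NeighborTable,
    d_thr: float = DEFAULT_D_THR,
    k_min: int = DEFAULT_K_MIN,
    *,
    dimension: int,
) -> int:
    """Largest k whose likelihood-ratio scan stays below ``d_thr``.

    Scans upward from ``k_min``; the first k whose statistic exceeds the
    threshold ends the scan and the previous k is returned (never less
    than ``k_min``; ``k_max`` if the threshold is never crossed).
    """
    if neighbors.k_max < k_min + 1:
        raise ValueError("neighbor table too small for k_min")
    volumes = _cumulative_volumes(neighbors, dimension)
    ks, dk = _dk_matrix(
        volumes, neighbors.indices, k_min, rows=np.asarray([point_index])
    )
    viol = dk[0] > d_thr
    if not viol.any():
        return neighbors.k_max
    first = int(np.argmax(viol))
    return max(k_min, int(ks[first]) - 1)


def estimate_densities(
    cs: ConfigurationSet,
    k_max: Optional[int] = None,
    d_thr: float = DEFAULT_D_THR,
    k_min: int = DEFAULT_K_MIN,
    neighbors: Optional[NeighborTable] = None,
) -> DensityEstimate:
    """Adaptive-k density estimate for every configuration.

    Densities are normalized by N so they integrate to roughly one over
    the torus; only ratios matter downstream.  ``neighbors`` may be
    supplied to reuse a precomputed table (its ``k_max`` then applies).
    """
    n = cs.n
    if k_max is None:
        k_max = min(n - 1, DEFAULT_K_MAX)
    if n < k_min + 2:
        raise ValueError(f"need at least k_min + 2 = {k_min + 2} points")
    if neighbors is None:
        neighbors = nearest_neighbors(cs, k_max)
    k_max = neighbors.k_max
    if k_max < k_min + 1:
        raise ValueError("k_max must exceed k_min")

    volumes = _cumulative_volumes(neighbors, cs.d)
    ks, dk = _dk_matrix(volumes, neighbors.indices, k_min)
    viol = dk > d_thr
    has_viol = viol.any(axis=1)
    first = viol.argmax(axis=1)
    k_sel = np.where(has_viol, np.maximum(k_min, k_min + first - 1), k_max)

    rows = np.arange(n)
    v_sel = volumes[rows, k_sel - 1]
    # duplicate stacks: fall back to the smallest k with nonzero volume
    zero = v_sel == 0
    if zero.any():
        positive = volumes > 0
        if not positive[zero].any(axis=1).all():
            bad = rows[zero][~positive[zero].any(axis=1)]
            raise ValueError(
                f"all {k_max} nearest neighbors coincide for points {bad.tolist()}"
            )
        k_first = positive.argmax(axis=1) + 1  # 1-based neighbour count
        k_sel = np.where(zero, k_first, k_sel)
        v_sel = volumes[rows, k_sel - 1]

    rho = k_sel / (n * v_sel)
    return DensityEstimate(rho=rho, k_selected=k_sel.astype(np.int64), V_k=v_sel)
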