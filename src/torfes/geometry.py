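"""Periodic geometry of torsion-angle space.

All angles live on the D-dimensional torus ``(-pi, pi]^D`` with the
per-dimension minimum-image metric.  This module provides wrapping,
distances, exact nearest-neighbour search, and hypersphere/shell volumes
used by the adaptive density estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import math

import numpy as np

__all__ = [
    "ConfigurationSet",
    "NeighborTable",
    "wrap_angles",
    "torus_distance",
    "pairwise_sq_dists",
    "nearest_neighbors",
    "radius_mean",
    "hypersphere_volume",
    "shell_volumes",
    "torus_volume",
    "average_density",
]

logger = logging.getLogger(__name__)

_TWO_PI = 2.0 * np.pi


def wrap_angles(x):
    """Wrap angles (radians) into the half-open interval ``(-pi, pi]``.

    Accepts scalars or arrays; raises ``ValueError`` on non-finite input.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("angles must be finite")
    # pi - (pi - x) mod 2pi lands exactly in (-pi, pi]
    wrapped = np.pi - np.mod(np.pi - x, _TWO_PI)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


@dataclass
class ConfigurationSet:
    """A sample of N configurations in D-dimensional torsion space.

    Parameters
    ----------
    angles : (N, D) array
        Torsion angles in radians; wrapped to ``(-pi, pi]`` on construction.
    times : (N,) array, optional
        Strictly increasing simulation times.
    """

    angles: np.ndarray
    times: Optional[np.ndarray] = None

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.ndim == 1:
            a = a[:, None]
        if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
            raise ValueError("angles must be a (N, D) array with N, D >= 1")
        self.angles = wrap_angles(a)
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            if t.shape != (a.shape[0],):
                raise ValueError("times must have shape (N,)")
            if np.any(np.diff(t) <= 0):
                raise ValueError("times must be strictly increasing")
            self.times = t

    @property
    def n(self) -> int:
        return self.angles.shape[0]

    @property
    def d(self) -> int:
        return self.angles.shape[1]

    def subset(self, indices) -> "ConfigurationSet":
        """Return the configurations at ``indices`` (order preserved)."""
        idx = np.asarray(indices)
        times = self.times[idx] if self.times is not None else None
        return ConfigurationSet(self.angles[idx], times)


@dataclass
class NeighborTable:
    """For each point, its ``k_max`` nearest other points on the torus.

    ``indices[i, l]`` is the (l+1)-th nearest neighbour of point i and
    ``distances[i, l]`` the corresponding torus distance; rows are sorted
    by ascending distance with ties broken by smaller index.  Self is
    excluded.
    """

    indices: np.ndarray
    distances: np.ndarray
    k_max: int = field(default=0)

    def __post_init__(self):
        if self.k_max == 0:
            self.k_max = self.indices.shape[1]
        if self.indices.shape != self.distances.shape:
            raise ValueError("indices and distances must have the same shape")


def torus_distance(a, b) -> float:
    """Minimum-image Euclidean distance between two torsion vectors."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    diff = np.abs(wrap_angles(a) - wrap_angles(b))
    diff = np.minimum(diff, _TWO_PI - diff)
    return float(np.sqrt(np.sum(diff * diff)))


def pairwise_sq_dists(query: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Squared minimum-image distances between two sets of wrapped angles.

    ``query`` is (m, D), ``ref`` is (n, D); the result is (m, n).
    Dimensions are accumulated in index order so that results are
    bit-reproducible across code paths.
    """
    m, d = query.shape
    n = ref.shape[0]
    if ref.shape[1] != d:
        raise ValueError("dimension mismatch")
    out = np.zeros((m, n), dtype=float)
    for k in range(d):
        diff = np.abs(query[:, k, None] - ref[None, :, k])
        np.minimum(diff, _TWO_PI - diff, out=diff)
        out += diff * diff
    return out


def _circle_embedding(x: np.ndarray) -> np.ndarray:
    """Per-dimension (cos, sin) embedding, shape (N, 2D).

    The chordal squared distance ``2D - 2 E_a . E_b`` lower-bounds the
    squared torus distance dimension by dimension (chord <= arc), so it
    can generate neighbour candidates via a single BLAS matmul.
    """
    return np.concatenate([np.cos(x), np.sin(x)], axis=1)


def _gathered_sq_dists(query: np.ndarray, cand_angles: np.ndarray) -> np.ndarray:
    """Exact squared torus distances for (m, M, D) candidate blocks.

    Accumulates dimensions in the same order as :func:`pairwise_sq_dists`
    so both code paths are bit-identical.
    """
    m, big_m, d = cand_angles.shape
    out = np.zeros((m, big_m), dtype=float)
    for k in range(d):
        diff = np.abs(query[:, None, k] - cand_angles[:, :, k])
        np.minimum(diff, _TWO_PI - diff, out=diff)
        out += diff * diff
    return out


def _row_exact_topk(
    x: np.ndarray, i: int, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact top-k of point i by (torus distance, index); fallback path."""
    d2 = pairwise_sq_dists(x[i : i + 1], x)[0]
    d2[i] = np.inf
    order = np.lexsort((np.arange(x.shape[0]), d2))[:k]
    return order, d2[order]


def nearest_neighbors(
    cs: ConfigurationSet, k_max: int, chunk_size: int = 4096
) -> NeighborTable:
    """Exact k-nearest-neighbour table under the torus metric.

    Candidates come from a kd-tree on the per-dimension (cos, sin)
    embedding, whose Euclidean (chordal) metric lower-bounds the torus
    metric, and are refined with exact minimum-image distances.  Rows
    where the bound cannot certify completeness (including exact distance
    ties at the candidate boundary) fall back to a full exact scan.  Ties
    in distance are resolved deterministically by smaller index.
    """
    from scipy.spatial import cKDTree

    x = cs.angles
    n = cs.n
    if not 1 <= k_max <= n - 1:
        raise ValueError(f"k_max must be in [1, N-1]; got {k_max} with N={n}")
    emb = _circle_embedding(x)
    tree = cKDTree(emb)
    k_query = min(n, k_max + 34)  # slack absorbs chord-vs-arc reordering
    indices = np.empty((n, k_max), dtype=np.int64)
    distances = np.empty((n, k_max), dtype=float)
    n_fallback = 0
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        m = stop - start
        dd, cand = tree.query(emb[start:stop], k=k_query)
        if k_query < n:
            # any point not among the candidates has chordal distance (and
            # hence torus distance) at least dd[:, -1], minus an fp margin
            boundary = dd[:, -1] ** 2 - 1e-9
        else:
            boundary = np.full(m, np.inf)
        d2e = _gathered_sq_dists(x[start:stop], x[cand])
        d2e[cand == np.arange(start, stop)[:, None]] = np.inf  # exclude self
        order = np.lexsort((cand, d2e), axis=1)[:, :k_max]
        sel = np.take_along_axis(cand, order, axis=1)
        sel_d2 = np.take_along_axis(d2e, order, axis=1)
        risky = np.nonzero(sel_d2[:, -1] >= boundary)[0]
        for r in risky:
            sel[r], sel_d2[r] = _row_exact_topk(x, start + r, k_max)
            n_fallback += 1
        indices[start:stop] = sel
        distances[start:stop] = np.sqrt(sel_d2)
    if n_fallback:
        logger.debug("nearest_neighbors: %d exact-row fallbacks", n_fallback)
    return NeighborTable(indices=indices, distances=distances, k_max=k_max)


def radius_mean(
    cs: ConfigurationSet,
    values: np.ndarray,
    radius: float,
    chunk_size: int = 4096,
) -> np.ndarray:
    """Mean of ``values`` over all points within ``radius`` of each point.

    The point itself is always included, so the result is defined
    everywhere.  Candidates are pruned with the chordal lower bound
    (kd-tree ball query on the circle embedding) and confirmed with exact
    minimum-image distances.
    """
    from scipy.spatial import cKDTree

    if radius <= 0:
        raise ValueError("radius must be positive")
    x = cs.angles
    n = cs.n
    values = np.asarray(values, dtype=float)
    if values.shape != (n,):
        raise ValueError("values must have shape (N,)")
    r2 = radius * radius
    emb = _circle_embedding(x)
    tree = cKDTree(emb)
    out = np.empty(n, dtype=float)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        m = stop - start
        lists = tree.query_ball_point(emb[start:stop], radius + 1e-9)
        lengths = np.fromiter((len(l) for l in lists), dtype=np.int64, count=m)
        cols = np.concatenate([np.asarray(l, dtype=np.int64) for l in lists])
        rows = np.repeat(np.arange(m), lengths)
        d2e = np.zeros(cols.shape[0])
        for k in range(cs.d):
            diff = np.abs(x[start + rows, k] - x[cols, k])
            np.minimum(diff, _TWO_PI - diff, out=diff)
            d2e += diff * diff
        ok = d2e <= r2
        sums = np.bincount(rows[ok], weights=values[cols[ok]], minlength=m)
        counts = np.bincount(rows[ok], minlength=m)
        out[start:stop] = sums / counts
    return out


def _int_power(r, d: int):
    """``r**d`` by binary exponentiation.

    IEEE multiplications round identically whether vectorized or scalar,
    so this gives bit-identical results across array and per-point code
    paths (plain ``**`` does not: numpy's vectorized pow and libm's
    scalar pow can differ in the last ulp).
    """
    result = None
    base = r
    e = d
    while e:
        if e & 1:
            result = base if result is None else result * base
        e >>= 1
        if e:
            base = base * base
    return result


def hypersphere_volume(d: int, r) -> float:
    """Volume of a D-ball of radius r: ``pi^{D/2} / Gamma(D/2 + 1) * r^D``."""
    if d < 1:
        raise ValueError("dimension must be >= 1")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be nonnegative")
    unit = math.pi ** (d / 2) / math.gamma(d / 2 + 1)
    out = unit * _int_power(r, d)
    return float(out) if out.ndim == 0 else out


def unit_ball_volume(d: int) -> float:
    """Volume of the unit D-ball."""
    return hypersphere_volume(d, 1.0)


def shell_volumes(distances: Sequence[float], d: int) -> np.ndarray:
    """Volumes of consecutive hyperspherical shells.

    ``v_l = V(r_l) - V(r_{l-1})`` with ``r_0 = 0``; partial sums telescope
    back to the enclosing sphere volume.
    """
    r = np.asarray(distances, dtype=float)
    if np.any(np.diff(r) < 0):
        raise ValueError("radii must be nondecreasing")
    v = hypersphere_volume(d, r)
    return np.diff(np.concatenate(([0.0], np.atleast_1d(v))))


def torus_volume(d: int) -> float:
    """Total volume of the D-torus, ``(2 pi)^D``."""
    if d < 1:
        raise ValueError("dimension must be >= 1")
    return _TWO_PI**d


def average_density(n: int, d: int) -> float:
    """Average sample density on the full D-torus, ``N / (2 pi)^D``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return n / torus_volume(d)
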