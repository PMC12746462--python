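"""Convergence and robustness diagnostics.

Two families of checks: time convergence of the 1D marginal free-energy
profiles (average absolute bin difference against the full-data profile)
and stability of the conformer classification against sample size
(cluster counts plus positional / energetic deviations of matched
centers relative to the largest-sample reference).  A conventional
low-dimensional reweighted histogram FES is included as an independent
reference for the per-point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .conformers import ClusterSet
from .constants import DEFAULT_TEMPERATURE, KB
from .geometry import ConfigurationSet, pairwise_sq_dists
from .pipeline import run_pipeline
from .reweight import BiasTable

__all__ = [
    "MarginalFES",
    "ConsistencyReport",
    "marginal_fes",
    "delta_F_M",
    "grid_reference_fes",
    "match_cluster_sets",
    "consistency_curve",
]

DEFAULT_N_HIST: int = 100


@dataclass
class MarginalFES:
    """1D free-energy profile of one torsion up to a time horizon."""

    torsion: int
    edges: np.ndarray  # (n_hist + 1,)
    F: np.ndarray  # (n_hist,), nan on empty bins
    occupied: np.ndarray  # (n_hist,) bool
    up_to_time: float


@dataclass
class ConsistencyReport:
    """Assembled diagnostics across time and sample size."""

    sizes: List[int]
    n_clusters: List[int]
    delta_d_bar: List[float]
    delta_F_bar: List[float]
    reference_size: int
    delta_F_curves: Dict[int, List[Tuple[float, float]]] = field(default_factory=dict)


def _weights(bias: Optional[BiasTable], temperature: float, n: int) -> np.ndarray:
    if bias is None:
        return np.ones(n)
    beta = 1.0 / (KB * temperature)
    e = beta * bias.total
    return np.exp(e - e.max())  # gauge shift cancels after min-zeroing


def marginal_fes(
    cs: ConfigurationSet,
    bias: Optional[BiasTable],
    torsion: int,
    up_to_time: float,
    n_hist: int = DEFAULT_N_HIST,
    temperature: float = DEFAULT_TEMPERATURE,
) -> MarginalFES:
    """Reweighted 1D histogram FES from data gathered up to ``up_to_time``."""
    if cs.times is None:
        raise ValueError("configuration set has no times")
    sel = cs.times <= up_to_time
    if not sel.any():
        raise ValueError(f"no configurations with time <= {up_to_time}")
    w = _weights(bias, temperature, cs.n)[sel]
    hist, edges = np.histogram(
        cs.angles[sel, torsion], bins=n_hist, range=(-np.pi, np.pi), weights=w
    )
    occupied = hist > 0
    f = np.full(n_hist, np.nan)
    f[occupied] = -KB * temperature * np.log(hist[occupied])
    f[occupied] -= np.nanmin(f[occupied])
    return MarginalFES(
        torsion=torsion, edges=edges, F=f, occupied=occupied, up_to_time=up_to_time
    )


def delta_F_M(
    cs: ConfigurationSet,
    bias: Optional[BiasTable],
    torsion: int,
    checkpoints: Sequence[float],
    n_hist: int = DEFAULT_N_HIST,
    temperature: float = DEFAULT_TEMPERATURE,
) -> List[Tuple[float, float]]:
    """Average absolute per-bin difference to the full-data marginal FES.

    Only bins occupied at both horizons contribute; the value at the
    final time is exactly zero.
    """
    if cs.times is None:
        raise ValueError("configuration set has no times")
    tau = float(cs.times[-1])
    ref = marginal_fes(cs, bias, torsion, tau, n_hist, temperature)
    curve = []
    for t in checkpoints:
        if not 0 < t <= tau:
            raise ValueError(f"checkpoint {t} outside (0, tau]")
        part = marginal_fes(cs, bias, torsion, t, n_hist, temperature)
        both = ref.occupied & part.occupied
        if not both.any():
            raise ValueError(f"no commonly occupied bins at t={t}")
        curve.append((t, float(np.mean(np.abs(ref.F[both] - part.F[both])))))
    return curve


def grid_reference_fes(
    cs: ConfigurationSet,
    bias: Optional[BiasTable],
    dims: Sequence[int],
    bins: int = DEFAULT_N_HIST,
    temperature: float = DEFAULT_TEMPERATURE,
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Conventional reweighted histogram FES on 1-3 chosen torsions.

    Returns (edges per dimension, F array with nan on empty bins,
    min-shifted to 0).  Resolution is ``2 pi / bins`` per dimension.
    """
    dims = list(dims)
    if not 1 <= len(dims) <= 3:
        raise ValueError("grid reference supports 1-3 dimensions")
    w = _weights(bias, temperature, cs.n)
    hist, edges = np.histogramdd(
        cs.angles[:, dims],
        bins=[bins] * len(dims),
        range=[(-np.pi, np.pi)] * len(dims),
        weights=w,
    )
    f = np.full_like(hist, np.nan)
    occ = hist > 0
    f[occ] = -KB * temperature * np.log(hist[occ])
    f[occ] -= np.nanmin(f[occ])
    return list(edges), f


def match_cluster_sets(
    c_n: ClusterSet, c_ref: ClusterSet
) -> Tuple[List[Tuple[int, int]], float, float]:
    """Pair each center with its torus-nearest reference center.

    Many-to-one pairing; returns the pair list and the mean positional
    and free-energy deviations (each set's F is already zeroed at its
    own minimum).
    """
    if c_n.d != c_ref.d:
        raise ValueError("cluster sets disagree on D")
    d2 = pairwise_sq_dists(c_n.center_coords, c_ref.center_coords)
    nearest = np.argmin(d2, axis=1)
    pairs = [(i, int(j)) for i, j in enumerate(nearest)]
    dd = np.sqrt(d2[np.arange(len(nearest)), nearest])
    df = np.abs(c_n.center_F - c_ref.center_F[nearest])
    return pairs, float(dd.mean()), float(df.mean())


def consistency_curve(
    cs: ConfigurationSet,
    bias: Optional[BiasTable],
    sizes: Sequence[int],
    seed: int,
    temperature: float = DEFAULT_TEMPERATURE,
    **pipeline_kwargs,
) -> ConsistencyReport:
    """Cluster-set stability against subsample size.

    For each size, a uniform random subsample (without replacement,
    seeded) is pushed through the full pipeline; the resulting cluster
    set is matched against the one from the largest size.
    """
    sizes = sorted(int(s) for s in sizes)
    if sizes[-1] > cs.n:
        raise ValueError("largest size exceeds available data")
    rng = np.random.default_rng(seed)
    cluster_sets = []
    for size in sizes:
        idx = np.sort(rng.choice(cs.n, size=size, replace=False))
        sub = cs.subset(idx)
        sub_bias = BiasTable(bias.values[idx]) if bias is not None else None
        _, _, _, clusters = run_pipeline(
            sub, bias=sub_bias, temperature=temperature, **pipeline_kwargs
        )
        cluster_sets.append(clusters)
    ref = cluster_sets[-1]
    n_clusters, dd_bar, df_bar = [], [], []
    for clusters in cluster_sets:
        _, dd, df = match_cluster_sets(clusters, ref)
        n_clusters.append(clusters.n_clusters)
        dd_bar.append(dd)
        df_bar.append(df)
    return ConsistencyReport(
        sizes=sizes,
        n_clusters=n_clusters,
        delta_d_bar=dd_bar,
        delta_F_bar=df_bar,
        reference_size=sizes[-1],
    )
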