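"""Convenience orchestration of the per-point FES and conformer pipeline."""

from __future__ import annotations

from typing import Optional, Tuple

from .conformers import (
    DEFAULT_MERGE_KT,
    DEFAULT_MIN_FRACTION,
    ClusterSet,
    cluster_conformers,
)
from .constants import DEFAULT_TEMPERATURE
from .geometry import ConfigurationSet, NeighborTable, nearest_neighbors
from .pak import (
    DEFAULT_D_THR,
    DEFAULT_K_MAX,
    DEFAULT_K_MIN,
    DensityEstimate,
    estimate_densities,
)
from .reweight import (
    DEFAULT_SMOOTHING_RADIUS,
    BiasTable,
    PerPointFES,
    per_point_free_energy,
    smooth_densities,
    zwanzig_reweight,
)

__all__ = ["compute_per_point_fes", "run_pipeline"]


def compute_per_point_fes(
    cs: ConfigurationSet,
    bias: Optional[BiasTable] = None,
    temperature: float = DEFAULT_TEMPERATURE,
    smoothing_radius: float = DEFAULT_SMOOTHING_RADIUS,
    d_thr: float = DEFAULT_D_THR,
    k_min: int = DEFAULT_K_MIN,
    k_max: Optional[int] = None,
    neighbors: Optional[NeighborTable] = None,
) -> Tuple[DensityEstimate, PerPointFES, NeighborTable]:
    """Densities -> reweighting -> smoothing -> free energies."""
    if k_max is None:
        k_max = min(cs.n - 1, DEFAULT_K_MAX)
    if neighbors is None:
        neighbors = nearest_neighbors(cs, k_max)
    density = estimate_densities(
        cs, d_thr=d_thr, k_min=k_min, neighbors=neighbors
    )
    if bias is None:
        bias = BiasTable.zeros(cs.n, cs.d)
    rho_star = zwanzig_reweight(density, bias, temperature)
    rho_bar = smooth_densities(cs, rho_star, smoothing_radius)
    fes = per_point_free_energy(rho_bar, temperature, rho_star=rho_star)
    return density, fes, neighbors


def run_pipeline(
    cs: ConfigurationSet,
    bias: Optional[BiasTable] = None,
    temperature: float = DEFAULT_TEMPERATURE,
    smoothing_radius: float = DEFAULT_SMOOTHING_RADIUS,
    d_thr: float = DEFAULT_D_THR,
    k_min: int = DEFAULT_K_MIN,
    k_max: Optional[int] = None,
    merge_threshold_kt: float = DEFAULT_MERGE_KT,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    neighbors: Optional[NeighborTable] = None,
) -> Tuple[DensityEstimate, PerPointFES, NeighborTable, ClusterSet]:
    """Full workflow through conformer classification."""
    density, fes, neighbors = compute_per_point_fes(
        cs,
        bias=bias,
        temperature=temperature,
        smoothing_radius=smoothing_radius,
        d_thr=d_thr,
        k_min=k_min,
        k_max=k_max,
        neighbors=neighbors,
    )
    clusters = cluster_conformers(
        cs,
        fes,
        neighbors,
        density.k_selected,
        temperature=temperature,
        merge_threshold_kt=merge_threshold_kt,
        min_fraction=min_fraction,
    )
    return density, fes, neighbors, clusters
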