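"""Density-peak conformer classification.

Peaks of the smoothed reweighted density become cluster centers; every
other configuration inherits the cluster of its nearest
higher-density point.  Basins separated by saddles less than a thermal
threshold above the shallower center are merged, and clusters holding
less than a population cutoff are discarded as spurious.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB
from .geometry import ConfigurationSet, NeighborTable, pairwise_sq_dists
from .reweight import PerPointFES

__all__ = [
    "ClusterSet",
    "find_density_peaks",
    "assign_memberships",
    "saddle_free_energies",
    "merge_shallow_clusters",
    "filter_small_clusters",
    "cluster_conformers",
]

logger = logging.getLogger(__name__)

DISCARDED: int = -1

DEFAULT_MERGE_KT: float = 1.0
DEFAULT_MIN_FRACTION: float = 0.01


@dataclass
class ClusterSet:
    """Conformers identified on a configuration sample.

    ``assignment[i]`` is the cluster id of configuration i or ``-1`` for
    discarded points.  ``center_F`` is relative to the global minimum
    center (the deepest conformer has F = 0).  ``saddle_F`` maps cluster
    id pairs ``(a, b)`` with a < b to the saddle free energy on the same
    scale as ``center_F``; pairs without border contact are absent.
    """

    center_indices: np.ndarray
    center_coords: np.ndarray
    center_F: np.ndarray
    assignment: np.ndarray
    populations: np.ndarray
    saddle_F: Dict[Tuple[int, int], float] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.center_indices)

    @property
    def d(self) -> int:
        return self.center_coords.shape[1]


def _density_rank(rho_bar: np.ndarray) -> np.ndarray:
    """Total order on points: descending density, ties by smaller index.

    ``rank[i] < rank[j]`` means i is treated as strictly denser than j.
    """
    n = rho_bar.shape[0]
    order = np.lexsort((np.arange(n), -rho_bar))
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    return rank


def find_density_peaks(
    fes: PerPointFES,
    neighbors: NeighborTable,
    k_selected: np.ndarray,
) -> np.ndarray:
    """Indices of points denser than everything in their selected-k neighbourhood.

    Exact density ties are broken by smaller index.
    """
    rho = fes.rho_bar
    n = rho.shape[0]
    centers = []
    for i in range(n):
        nb = neighbors.indices[i, : k_selected[i]]
        r_nb = rho[nb]
        if np.all((r_nb < rho[i]) | ((r_nb == rho[i]) & (nb > i))):
            centers.append(i)
    return np.asarray(centers, dtype=np.int64)


def assign_memberships(
    cs: ConfigurationSet,
    fes: PerPointFES,
    neighbors: NeighborTable,
    centers: np.ndarray,
) -> np.ndarray:
    """Propagate cluster labels down the density ordering.

    Each non-center point joins the cluster of its nearest point of
    strictly higher density (density ties broken by index).  The
    neighbour table is scanned first; the rare points whose higher-density
    neighbour lies beyond ``k_max`` fall back to an exact search.
    """
    if len(centers) == 0:
        raise ValueError("no cluster centers")
    rho = fes.rho_bar
    n = rho.shape[0]
    rank = _density_rank(rho)
    order = np.argsort(rank)
    labels = np.full(n, DISCARDED, dtype=np.int64)
    for cid, c in enumerate(centers):
        labels[c] = cid
    n_fallback = 0
    for i in order:
        if labels[i] != DISCARDED:
            continue
        nb = neighbors.indices[i]
        higher = nb[rank[nb] < rank[i]]
        if higher.size:
            parent = higher[0]  # rows sorted by (distance, index)
        else:
            cand = np.nonzero(rank < rank[i])[0]
            d2 = pairwise_sq_dists(cs.angles[i : i + 1], cs.angles[cand])[0]
            parent = cand[np.lexsort((cand, d2))[0]]
            n_fallback += 1
        labels[i] = labels[parent]
    if n_fallback:
        logger.debug("assign_memberships: %d exact-search fallbacks", n_fallback)
    return labels


def saddle_free_energies(
    fes: PerPointFES,
    neighbors: NeighborTable,
    k_selected: np.ndarray,
    assignment: np.ndarray,
) -> Dict[Tuple[int, int], float]:
    """Saddle free energy between every pair of border-touching clusters.

    A point of cluster c is a border point toward c' when a point of c'
    lies within its selected-k neighbourhood; the saddle free energy is
    the minimum F (maximum density) over the border points collected from
    both sides.
    """
    saddles: Dict[Tuple[int, int], float] = {}
    f = fes.F
    n = f.shape[0]
    for i in range(n):
        li = assignment[i]
        if li == DISCARDED:
            continue
        nb = neighbors.indices[i, : k_selected[i]]
        foreign = np.unique(assignment[nb])
        for lj in foreign:
            if lj == DISCARDED or lj == li:
                continue
            key = (int(min(li, lj)), int(max(li, lj)))
            if key not in saddles or f[i] < saddles[key]:
                saddles[key] = float(f[i])
    return saddles


def _barrier(saddle_f: float, f_a: float, f_b: float) -> float:
    """Barrier as seen from the shallower basin."""
    return saddle_f - max(f_a, f_b)


def merge_shallow_clusters(
    clusters: ClusterSet,
    temperature: float = DEFAULT_TEMPERATURE,
    threshold_kt: float = DEFAULT_MERGE_KT,
) -> ClusterSet:
    """Iteratively merge cluster pairs across statistically shallow saddles.

    The pair with the smallest barrier (saddle minus the higher of the
    two center free energies) merges first, while that barrier is below
    ``threshold_kt * kB * T``; the merged cluster keeps the lower-F
    center and inherits the denser saddle toward every third cluster.
    """
    threshold = threshold_kt * KB * temperature
    center_idx = list(map(int, clusters.center_indices))
    center_coords = [c for c in clusters.center_coords]
    center_f = list(map(float, clusters.center_F))
    assignment = clusters.assignment.copy()
    saddles = dict(clusters.saddle_F)
    alive = set(range(len(center_idx)))

    while len(alive) > 1:
        best = None
        for (a, b), sf in saddles.items():
            bar = _barrier(sf, center_f[a], center_f[b])
            if best is None or bar < best[0] or (bar == best[0] and (a, b) < best[1]):
                best = (bar, (a, b))
        if best is None or best[0] >= threshold:
            break
        a, b = best[1]
        keep, drop = (a, b) if center_f[a] <= center_f[b] else (b, a)
        if center_f[a] == center_f[b]:
            keep, drop = min(a, b), max(a, b)
        assignment[assignment == drop] = keep
        alive.discard(drop)
        merged: Dict[Tuple[int, int], float] = {}
        for (x, y), sf in saddles.items():
            x2 = keep if x == drop else x
            y2 = keep if y == drop else y
            if x2 == y2:
                continue
            key = (min(x2, y2), max(x2, y2))
            if key not in merged or sf < merged[key]:
                merged[key] = sf
        saddles = merged

    return _relabel(
        assignment, center_idx, center_coords, center_f, sorted(alive), saddles
    )


def filter_small_clusters(
    clusters: ClusterSet,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> ClusterSet:
    """Discard clusters with population strictly below ``min_fraction * N``.

    Members of removed clusters are marked discarded, not reassigned.
    """
    n = clusters.assignment.shape[0]
    cutoff = min_fraction * n
    keep = [c for c in range(clusters.n_clusters) if clusters.populations[c] >= cutoff]
    if not keep:
        raise ValueError("all clusters fall below the population cutoff")
    assignment = clusters.assignment.copy()
    for c in range(clusters.n_clusters):
        if c not in keep:
            assignment[assignment == c] = DISCARDED
    saddles = {
        (a, b): sf
        for (a, b), sf in clusters.saddle_F.items()
        if a in keep and b in keep
    }
    return _relabel(
        assignment,
        list(map(int, clusters.center_indices)),
        [c for c in clusters.center_coords],
        list(map(float, clusters.center_F)),
        keep,
        saddles,
    )


def _relabel(assignment, center_idx, center_coords, center_f, alive, saddles) -> ClusterSet:
    """Compact cluster ids to 0..K-1 ordered by ascending center F."""
    alive = sorted(alive, key=lambda c: (center_f[c], c))
    remap = {old: new for new, old in enumerate(alive)}
    new_assignment = np.full_like(assignment, DISCARDED)
    for old, new in remap.items():
        new_assignment[assignment == old] = new
    new_saddles = {}
    for (a, b), sf in saddles.items():
        if a in remap and b in remap:
            x, y = remap[a], remap[b]
            new_saddles[(min(x, y), max(x, y))] = sf
    pops = np.bincount(
        new_assignment[new_assignment != DISCARDED], minlength=len(alive)
    )
    return ClusterSet(
        center_indices=np.asarray([center_idx[c] for c in alive], dtype=np.int64),
        center_coords=np.asarray([center_coords[c] for c in alive], dtype=float),
        center_F=np.asarray([center_f[c] for c in alive], dtype=float),
        assignment=new_assignment,
        populations=pops,
        saddle_F=new_saddles,
    )


def cluster_conformers(
    cs: ConfigurationSet,
    fes: PerPointFES,
    neighbors: NeighborTable,
    k_selected: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    merge_threshold_kt: float = DEFAULT_MERGE_KT,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> ClusterSet:
    """Full classification: peaks, membership, saddles, merging, filtering.

    Conformer free energies are reported relative to the deepest retained
    center (which gets exactly 0).
    """
    centers = find_density_peaks(fes, neighbors, k_selected)
    assignment = assign_memberships(cs, fes, neighbors, centers)
    # after membership propagation the center is the minimum-F point of
    # its cluster by construction of the density ordering
    saddles = saddle_free_energies(fes, neighbors, k_selected, assignment)
    pops = np.bincount(assignment, minlength=len(centers))
    provisional = ClusterSet(
        center_indices=centers,
        center_coords=cs.angles[centers],
        center_F=fes.F[centers],
        assignment=assignment,
        populations=pops,
        saddle_F=saddles,
    )
    merged = merge_shallow_clusters(provisional, temperature, merge_threshold_kt)
    final = filter_small_clusters(merged, min_fraction)
    shift = final.center_F.min()
    final.center_F = final.center_F - shift
    final.saddle_F = {k: v - shift for k, v in final.saddle_F.items()}
    logger.info(
        "cluster_conformers: %d peaks -> %d after merge -> %d after filter",
        len(centers),
        merged.n_clusters,
        final.n_clusters,
    )
    return final
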