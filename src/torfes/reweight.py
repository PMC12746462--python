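"""Final-bias evaluation, exponential reweighting, and per-point free energies.

The deposited metadynamics bias (one independent 1D bias per torsion) is
treated as quasi-static: each configuration is paired with the total
bias deposited by the end of the run, evaluated at its coordinates.
Biased densities are reweighted by ``exp(beta * sum_t V_t)``, smoothed
over fixed-radius hyperspherical neighbourhoods to tame the exponential
noise, and inverted to free energies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB
from .geometry import ConfigurationSet, radius_mean, wrap_angles
from .pak import DensityEstimate

__all__ = [
    "HillRecord",
    "BiasTable",
    "PerPointFES",
    "evaluate_final_bias",
    "zwanzig_reweight",
    "smooth_densities",
    "per_point_free_energy",
]

logger = logging.getLogger(__name__)

DEFAULT_SMOOTHING_RADIUS: float = 0.1

# keep exponentials representable; any common shift cancels in F
_LOG_GUARD = 600.0


@dataclass
class HillRecord:
    """One deposited Gaussian bias hill on a single torsion."""

    time: float
    center: float
    sigma: float
    height: float
    bias_factor: Optional[float] = None

    def __post_init__(self):
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"hill sigma must be positive, got {self.sigma}")
        if self.height < 0:
            raise ValueError("hill height must be nonnegative")
        if self.bias_factor is not None and self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        self.center = float(wrap_angles(self.center))


@dataclass
class BiasTable:
    """Final bias of each torsion evaluated at each configuration (kJ/mol)."""

    values: np.ndarray  # (N, D)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("bias values must be (N, D)")
        if not np.all(np.isfinite(v)):
            raise ValueError("bias values must be finite")
        self.values = v

    @property
    def total(self) -> np.ndarray:
        """Per-configuration sum over torsions, shape (N,)."""
        return self.values.sum(axis=1)

    @classmethod
    def zeros(cls, n: int, d: int) -> "BiasTable":
        return cls(np.zeros((n, d)))


@dataclass
class PerPointFES:
    """Reweighted, smoothed densities and per-point free energies."""

    rho_star: np.ndarray
    rho_bar: np.ndarray
    F: np.ndarray
    temperature: float

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)

    @property
    def n(self) -> int:
        return self.F.shape[0]


def evaluate_final_bias(
    hills: Sequence[Sequence[HillRecord]],
    cs: ConfigurationSet,
    well_tempered_rescale: bool = False,
    hill_chunk: int = 2048,
) -> BiasTable:
    """Sum of deposited Gaussians per torsion at each configuration.

    ``hills`` holds one hill list per torsion.  Angular offsets use the
    minimum image.  With ``well_tempered_rescale`` each hill is scaled by
    ``gamma / (gamma - 1)`` (for hill files storing unscaled heights).
    """
    if len(hills) != cs.d:
        raise ValueError(
            f"got hill lists for {len(hills)} torsions but data has D={cs.d}"
        )
    values = np.zeros((cs.n, cs.d))
    for t, hill_list in enumerate(hills):
        if not hill_list:
            continue
        gamma = np.asarray(
            [h.bias_factor if h.bias_factor is not None else np.nan for h in hill_list]
        )
        heights = np.asarray([h.height for h in hill_list], dtype=float)
        if well_tempered_rescale:
            if np.isnan(gamma).any():
                raise ValueError("well-tempered rescale requires bias factors")
            heights = heights * gamma / (gamma - 1.0)
        centers = np.asarray([h.center for h in hill_list], dtype=float)
        sigmas = np.asarray([h.sigma for h in hill_list], dtype=float)
        angle = cs.angles[:, t]
        for start in range(0, len(hill_list), hill_chunk):
            stop = min(start + hill_chunk, len(hill_list))
            delta = np.abs(angle[:, None] - centers[None, start:stop])
            np.minimum(delta, 2.0 * np.pi - delta, out=delta)
            values[:, t] += np.exp(
                -0.5 * (delta / sigmas[None, start:stop]) ** 2
            ) @ heights[start:stop]
    return BiasTable(values)


def zwanzig_reweight(
    density: DensityEstimate,
    bias: BiasTable,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """Reweighted densities ``rho* = rho * exp(beta * total bias)``.

    If the exponent would overflow, a common shift is subtracted; this is
    a pure gauge that cancels in free-energy differences.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if bias.values.shape[0] != density.n:
        raise ValueError("bias table and density estimate disagree on N")
    beta = 1.0 / (KB * temperature)
    log_rho_star = np.log(density.rho) + beta * bias.total
    shift = max(0.0, float(log_rho_star.max()) - _LOG_GUARD)
    if shift > 0:
        logger.info("zwanzig_reweight: applying overflow gauge shift %.3g", shift)
    return np.exp(log_rho_star - shift)


def smooth_densities(
    cs: ConfigurationSet,
    rho_star: np.ndarray,
    radius: float = DEFAULT_SMOOTHING_RADIUS,
) -> np.ndarray:
    """Average ``rho*`` over hyperspherical domains of the given radius.

    The arithmetic mean includes the point itself, so isolated points
    keep their own value.
    """
    return radius_mean(cs, rho_star, radius)


def per_point_free_energy(
    rho_bar: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    rho_star: Optional[np.ndarray] = None,
) -> PerPointFES:
    """Free energy per configuration, ``F = -kB T ln(rho_bar)``, min-shifted to 0."""
    rho_bar = np.asarray(rho_bar, dtype=float)
    bad = np.nonzero(~(rho_bar > 0))[0]
    if bad.size:
        raise ValueError(
            f"smoothed densities must be positive; offending indices: {bad[:10].tolist()}"
        )
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    f = -KB * temperature * np.log(rho_bar)
    f -= f.min()
    if rho_star is None:
        rho_star = rho_bar.copy()
    return PerPointFES(
        rho_star=np.asarray(rho_star, dtype=float),
        rho_bar=rho_bar,
        F=f,
        temperature=temperature,
    )
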