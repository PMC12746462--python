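"""Synthetic torus landscapes with analytic density and free-energy oracles.

Mixtures of product von Mises components provide ground-truth multimodal
densities on the D-torus; truncated Fourier series provide smooth
per-torsion biases.  Samplers cover the unbiased ensemble (i.i.d.) and
the biased ensemble ``p(s) * exp(beta * sum_t V_t)`` (Metropolis walk),
so the full reweighting pipeline can be validated without any molecular
dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
from scipy.special import i0e, logsumexp

from .constants import DEFAULT_TEMPERATURE, KB
from .geometry import ConfigurationSet, wrap_angles
from .reweight import BiasTable

__all__ = [
    "TorusMixture",
    "SyntheticBias",
    "analytic_density",
    "analytic_free_energy",
    "sample_unbiased",
    "sample_biased",
    "bias_table_for",
    "marginal_flattening_bias",
    "ala2_like",
    "sdz_like",
    "high_d",
    "two_mode_mixture",
]

logger = logging.getLogger(__name__)


@dataclass
class TorusMixture:
    """Mixture of product von Mises components on the D-torus.

    ``weights`` is (C,), ``means`` and ``kappas`` are (C, D); weights are
    normalized on construction.
    """

    weights: np.ndarray
    means: np.ndarray
    kappas: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        mu = np.atleast_2d(np.asarray(self.means, dtype=float))
        kap = np.atleast_2d(np.asarray(self.kappas, dtype=float))
        if np.any(w <= 0):
            raise ValueError("component weights must be positive")
        if mu.shape != kap.shape or mu.shape[0] != w.shape[0]:
            raise ValueError("inconsistent mixture shapes")
        if np.any(kap <= 0):
            raise ValueError("concentrations must be positive")
        self.weights = w / w.sum()
        self.means = wrap_angles(mu)
        self.kappas = kap

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def log_density(self, points: np.ndarray) -> np.ndarray:
        """Log density at ``points`` ((N, D) or (D,)), exact normalization."""
        x = np.atleast_2d(np.asarray(points, dtype=float))
        if x.shape[1] != self.d:
            raise ValueError("dimension mismatch")
        # log vM(x; mu, k) = k cos(x-mu) - log(2 pi I0(k)), with
        # log I0(k) = log(i0e(k)) + k for overflow safety
        log_norm = np.log(2.0 * np.pi) + np.log(i0e(self.kappas)) + self.kappas
        per_comp = (
            self.kappas[None, :, :] * np.cos(x[:, None, :] - self.means[None, :, :])
            - log_norm[None, :, :]
        ).sum(axis=2)
        return logsumexp(per_comp + np.log(self.weights)[None, :], axis=1)

    def marginal_log_density(self, torsion: int, gamma: np.ndarray) -> np.ndarray:
        """Log marginal density of a single torsion on a 1D grid."""
        g = np.asarray(gamma, dtype=float)
        kap = self.kappas[:, torsion]
        mu = self.means[:, torsion]
        log_norm = np.log(2.0 * np.pi) + np.log(i0e(kap)) + kap
        per = kap[:, None] * np.cos(g[None, :] - mu[:, None]) - log_norm[:, None]
        return logsumexp(per + np.log(self.weights)[:, None], axis=0)


def analytic_density(mixture: TorusMixture, points) -> np.ndarray:
    """Exact mixture density at the given points, rad^-D."""
    out = np.exp(mixture.log_density(points))
    return out


def analytic_free_energy(
    mixture: TorusMixture,
    points,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """Ground-truth free energy ``-kB T ln p``, shifted to min 0 over ``points``."""
    f = -KB * temperature * mixture.log_density(points)
    return f - f.min()


def sample_unbiased(
    mixture: TorusMixture,
    n: int,
    seed: int,
    with_times: bool = True,
) -> ConfigurationSet:
    """I.i.d. draws from the mixture; bit-reproducible for a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    comps = rng.choice(mixture.n_components, size=n, p=mixture.weights)
    angles = rng.vonmises(mixture.means[comps], mixture.kappas[comps])
    times = np.arange(1.0, n + 1.0) if with_times else None
    return ConfigurationSet(angles, times)


@dataclass
class SyntheticBias:
    """Smooth 2pi-periodic per-torsion bias as a truncated Fourier series.

    ``V_t(g) = sum_m cos_coeffs[t, m-1] cos(m g) + sin_coeffs[t, m-1] sin(m g)``
    in kJ/mol.
    """

    cos_coeffs: np.ndarray  # (D, M)
    sin_coeffs: np.ndarray  # (D, M)

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.cos_coeffs, dtype=float))
        s = np.atleast_2d(np.asarray(self.sin_coeffs, dtype=float))
        if c.shape != s.shape:
            raise ValueError("coefficient arrays must share a shape")
        self.cos_coeffs = c
        self.sin_coeffs = s

    @property
    def d(self) -> int:
        return self.cos_coeffs.shape[0]

    def evaluate(self, angles: np.ndarray) -> np.ndarray:
        """Per-torsion bias values, shape (N, D), for angles (N, D)."""
        x = np.atleast_2d(np.asarray(angles, dtype=float))
        if x.shape[1] != self.d:
            raise ValueError("dimension mismatch")
        m = np.arange(1, self.cos_coeffs.shape[1] + 1)
        phases = x[:, :, None] * m[None, None, :]
        return (
            np.cos(phases) * self.cos_coeffs[None, :, :]
            + np.sin(phases) * self.sin_coeffs[None, :, :]
        ).sum(axis=2)

    @classmethod
    def zeros(cls, d: int, n_harmonics: int = 1) -> "SyntheticBias":
        return cls(np.zeros((d, n_harmonics)), np.zeros((d, n_harmonics)))


def bias_table_for(cs: ConfigurationSet, bias: SyntheticBias) -> BiasTable:
    """Exact per-torsion bias evaluated at each configuration."""
    if bias.d != cs.d:
        raise ValueError("bias and configuration set disagree on D")
    return BiasTable(bias.evaluate(cs.angles))


def marginal_flattening_bias(
    mixture: TorusMixture,
    temperature: float = DEFAULT_TEMPERATURE,
    n_harmonics: int = 4,
    strength: float = 1.0,
    n_grid: int = 512,
) -> SyntheticBias:
    """Per-torsion bias proportional to minus the marginal free energy.

    Mimics a converged concurrent well-tempered bias: the deposited bias
    is largest where the marginal density is highest, so each torsion's
    marginal of the biased ensemble ``p * exp(-beta V)`` becomes (nearly)
    flat at ``strength = 1``.  Coefficients come from a Fourier fit of
    ``kB T ln p_t`` on a fine grid.
    """
    # sample on [0, 2pi) so rfft coefficients align with cos(m g), sin(m g)
    grid = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)
    cos_c = np.zeros((mixture.d, n_harmonics))
    sin_c = np.zeros((mixture.d, n_harmonics))
    for t in range(mixture.d):
        v = strength * KB * temperature * mixture.marginal_log_density(t, grid)
        coeffs = np.fft.rfft(v) / n_grid
        for m in range(1, n_harmonics + 1):
            cos_c[t, m - 1] = 2.0 * coeffs[m].real
            sin_c[t, m - 1] = -2.0 * coeffs[m].imag
    return SyntheticBias(cos_c, sin_c)


def sample_biased(
    mixture: TorusMixture,
    bias: SyntheticBias,
    n: int,
    seed: int,
    step: float = 0.5,
    burn_in: int = 5000,
    thinning: int = 10,
    temperature: float = DEFAULT_TEMPERATURE,
    with_times: bool = True,
    return_stats: bool = False,
):
    """Metropolis random walk targeting ``p(s) * exp(-beta * sum_t V_t)``.

    ``bias`` plays the role of the deposited (penalty) metadynamics
    bias: regions with positive bias are sampled less, and feeding the
    same bias table to the reweighting stage recovers ``p``.  Proposals
    are isotropic Gaussian steps wrapped onto the torus.  Returns a
    ``ConfigurationSet`` (and an info dict with the acceptance rate when
    ``return_stats`` is set).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    if bias.d != mixture.d:
        raise ValueError("bias and mixture disagree on D")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * temperature)
    d = mixture.d

    def log_target(x: np.ndarray) -> float:
        lp = mixture.log_density(x[None, :])[0]
        return lp - beta * bias.evaluate(x[None, :])[0].sum()

    x = mixture.means[0].copy()
    lt = log_target(x)
    total_steps = burn_in + n * thinning
    # draw all step randomness upfront for speed and reproducibility
    proposals = rng.normal(0.0, step, size=(total_steps, d))
    log_u = np.log(rng.random(total_steps))
    samples = np.empty((n, d))
    accepted = 0
    kept = 0
    for it in range(total_steps):
        y = wrap_angles(x + proposals[it])
        lt_y = log_target(y)
        if lt_y - lt >= log_u[it]:
            x, lt = y, lt_y
            accepted += 1
        if it >= burn_in and (it - burn_in) % thinning == thinning - 1:
            samples[kept] = x
            kept += 1
    assert kept == n
    rate = accepted / total_steps
    logger.info("sample_biased: acceptance rate %.3f over %d steps", rate, total_steps)
    times = np.arange(1.0, n + 1.0) if with_times else None
    cs = ConfigurationSet(samples, times)
    if return_stats:
        return cs, {"acceptance_rate": rate, "n_steps": total_steps}
    return cs


# ---------------------------------------------------------------------------
# fixture presets


def ala2_like() -> TorusMixture:
    """2D, three well-separated modes (alanine-dipeptide-like scale)."""
    return TorusMixture(
        weights=[0.5, 0.3, 0.2],
        means=[[-1.5, 1.0], [1.2, -0.8], [-2.8, -2.6]],
        kappas=[[12.0, 12.0], [12.0, 12.0], [12.0, 12.0]],
    )


def sdz_like() -> TorusMixture:
    """4D, eight modes on a sign lattice with one pi-shifted dimension."""
    means = []
    for s1 in (-1, 1):
        for s2 in (-1, 1):
            for s3 in (-1, 1):
                mu4 = 0.0 if s1 * s2 * s3 > 0 else np.pi
                means.append([2.0 * s1, 2.0 * s2, 2.0 * s3, mu4])
    weights = [1.3, 1.15, 1.05, 1.0, 0.95, 0.9, 0.85, 0.8]
    kappas = np.full((8, 4), 16.0)
    return TorusMixture(weights=weights, means=means, kappas=kappas)


def high_d() -> TorusMixture:
    """7D, six modes; desk-scale stand-in for a solvated flexible molecule."""
    rng = np.random.default_rng(20260905)
    means = rng.uniform(-np.pi, np.pi, size=(6, 7))
    # push modes apart: greedy jitter until pairwise torus distance >= 2
    for _ in range(200):
        diff = np.abs(means[:, None, :] - means[None, :, :])
        diff = np.minimum(diff, 2 * np.pi - diff)
        dist = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(dist, np.inf)
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        if dist[i, j] >= 2.0:
            break
        means[i] = wrap_angles(means[i] + rng.uniform(-0.5, 0.5, size=7))
    return TorusMixture(
        weights=np.linspace(1.2, 0.8, 6),
        means=means,
        kappas=np.full((6, 7), 8.0),
    )


def two_mode_mixture(kappa: float, d: int = 1) -> TorusMixture:
    """Equal-weight antipodal two-mode mixture (modes at 0 and pi)."""
    means = np.zeros((2, d))
    means[1, 0] = np.pi
    return TorusMixture(
        weights=[0.5, 0.5],
        means=means,
        kappas=np.full((2, d), kappa),
    )


def barrier_kappa(target_kt: float, d: int = 1) -> float:
    """Concentration giving a two-mode mixture the requested barrier (in kT).

    The barrier is ``ln(rho_peak / rho_saddle)`` of the analytic density,
    with the saddle at pi/2 along the first dimension.
    """
    from scipy.optimize import brentq

    def barrier(kappa: float) -> float:
        mix = two_mode_mixture(kappa, d)
        peak = np.zeros((1, d))
        saddle = np.zeros((1, d))
        saddle[0, 0] = np.pi / 2
        return float(mix.log_density(peak)[0] - mix.log_density(saddle)[0])

    return brentq(lambda k: barrier(k) - target_kt, 1e-3, 50.0, xtol=1e-10)
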