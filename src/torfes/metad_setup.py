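"""Hill-width heuristic from a short unbiased trajectory.

Each torsion's sampled marginal is fitted with a Gaussian mixture
(component count by BIC); the narrowest component width is the minimum
reference width and the suggested metadynamics hill width is a quarter
of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from sklearn.mixture import GaussianMixture

from .geometry import ConfigurationSet, wrap_angles

__all__ = ["HillWidthSuggestion", "suggest_hill_widths"]

MIN_SAMPLES: int = 100


@dataclass
class HillWidthSuggestion:
    torsion: int
    min_reference_width: float
    suggested_width: float
    n_components: int


def _fit_min_width(x: np.ndarray, max_components: int) -> tuple[float, int]:
    """Smallest component std of the BIC-best Gaussian mixture fit."""
    # unwrap about the circular mean so wrap-around does not split modes
    mu = np.arctan2(np.sin(x).mean(), np.cos(x).mean())
    y = wrap_angles(x - mu).reshape(-1, 1)
    best = None
    for n in range(1, max_components + 1):
        gm = GaussianMixture(n_components=n, random_state=0, n_init=1)
        gm.fit(y)
        bic = gm.bic(y)
        if best is None or bic < best[0]:
            widths = np.sqrt(gm.covariances_.ravel())
            best = (bic, float(widths.min()), n)
    return best[1], best[2]


def suggest_hill_widths(
    unbiased: ConfigurationSet, max_components: int = 6
) -> List[HillWidthSuggestion]:
    """Suggested hill width per torsion: minimum reference width / 4."""
    if unbiased.n < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {unbiased.n}")
    out = []
    for t in range(unbiased.d):
        x = unbiased.angles[:, t]
        if np.ptp(x) == 0:
            raise ValueError(f"torsion {t} marginal is degenerate (constant)")
        width, n_comp = _fit_min_width(x, max_components)
        out.append(
            HillWidthSuggestion(
                torsion=t,
                min_reference_width=width,
                suggested_width=width / 4.0,
                n_components=n_comp,
            )
        )
    return out
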