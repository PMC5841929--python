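"""Circular statistics for spike-phase analysis.

Angles are in radians internally; helpers accept/return degrees where the
phase-locking interface works in degrees.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0, i1


def resultant_vector(alpha: np.ndarray):
    """Mean resultant vector of angles (radians): returns (r, mean_angle)."""
    alpha = np.asarray(alpha, dtype=float)
    if len(alpha) == 0:
        return float("nan"), float("nan")
    C = np.cos(alpha).mean()
    S = np.sin(alpha).mean()
    r = float(np.hypot(C, S))
    mu = float(np.arctan2(S, C)) % (2 * np.pi)
    return r, mu


def rayleigh_test(alpha: np.ndarray) -> float:
    """Rayleigh test p-value for non-uniformity of circular data.

    Uses the standard refined approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)) with R = n*r,
    accurate for small and large n alike.
    """
    alpha = np.asarray(alpha, dtype=float)
    n = len(alpha)
    if n == 0:
        return float("nan")
    r, _ = resultant_vector(alpha)
    R = n * r
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n))
    return float(min(max(p, 0.0), 1.0))


def von_mises_r(kappa: float) -> float:
    """Population mean resultant length of a von Mises distribution,
    I1(kappa)/I0(kappa)."""
    if kappa == 0:
        return 0.0
    return float(i1(kappa) / i0(kappa))


def kl_from_uniform(hist: np.ndarray) -> float:
    """KL divergence (nats) of a probability histogram from uniform;
    zero bins contribute 0."""
    h = np.asarray(hist, dtype=float)
    n = len(h)
    pos = h > 0
    return float(np.sum(h[pos] * np.log(h[pos] * n)))
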