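"""Figure helpers for population-vector and ripple results."""

from __future__ import annotations

import numpy as np


def plot_pv_matrix(pm, ax=None):
    """Population-vector Spearman matrix with quadrant separators."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    n = pm.n_bins
    im = ax.imshow(pm.corr, vmin=-1, vmax=1, cmap="viridis", origin="lower")
    ax.axhline(n - 0.5, color="w", lw=0.8)
    ax.axvline(n - 0.5, color="w", lw=0.8)
    ax.set_xlabel("track bin (left | right)")
    ax.set_ylabel("track bin (left | right)")
    ax.figure.colorbar(im, ax=ax, label="Spearman rho")
    return ax


def plot_distance_profiles(profiles, labels=None, ax=None):
    """Mean correlation vs track distance with SEM shading."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    labels = labels or [p.quadrant_set for p in profiles]
    for prof, label in zip(profiles, labels):
        ok = np.isfinite(prof.mean_corr)
        d = prof.distance_cm[ok]
        m = prof.mean_corr[ok]
        s = np.where(np.isfinite(prof.sem_corr[ok]), prof.sem_corr[ok], 0.0)
        ax.plot(d, m, label=label)
        ax.fill_between(d, m - s, m + s, alpha=0.3)
    ax.set_xlabel("track distance (cm)")
    ax.set_ylabel("mean Spearman rho")
    ax.legend(frameon=False)
    return ax
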