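"""Post-sorting quality control and pyramidal-cell classification.

Units are excluded when refractory-period violations exceed 0.5% of
spikes, when they fire fewer than 50 spikes, or when their isolation
distance is below 10. Surviving units are classified as pyramidal cells
when the mean spike width exceeds 200 microseconds and the complex spike
index is at least 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DataError

# exclusion / classification thresholds
MAX_ISI_VIOLATION_FRAC = 0.005
MIN_SPIKES = 50
MIN_ISOLATION_DISTANCE = 10.0
PYRAMIDAL_MIN_WIDTH_US = 200.0
PYRAMIDAL_MIN_CSI = 5.0


@dataclass
class UnitQC:
    unit_id: str
    isi_violation_frac: float
    n_spikes: int
    isolation_distance: float
    csi: float
    width_us: float
    status: str = "included"      # "included" | "excluded"
    cell_class: str = "other"     # "pyramidal" | "other"


def isi_violation_fraction(t: np.ndarray, min_isi_ms: float = 2.0) -> float:
    """Fraction of *spikes* whose preceding inter-spike interval is below
    ``min_isi_ms`` (denominator is the spike count, not the ISI count)."""
    t = np.asarray(t, dtype=float)
    if len(t) < 2:
        raise DataError("ISI violation fraction undefined for <2 spikes")
    isi_ms = np.diff(t) * 1000.0
    return float(np.count_nonzero(isi_ms < min_isi_ms)) / len(t)


def isolation_distance(cluster_features: np.ndarray,
                       noise_features: np.ndarray,
                       ridge_frac: float = 1e-6) -> float:
    """Mahalanobis isolation distance of a cluster from non-cluster events.

    With n cluster spikes, the value is the squared Mahalanobis distance
    (w.r.t. the cluster mean and covariance) of the n-th closest noise
    spike. Larger is better separated. If fewer than n noise spikes exist
    the cluster is unbounded from the noise and +inf is returned with a
    warning; a singular covariance is ridge-regularised.
    """
    X = np.atleast_2d(np.asarray(cluster_features, dtype=float))
    N = np.atleast_2d(np.asarray(noise_features, dtype=float))
    n = len(X)
    if n < 2:
        raise DataError("need >=2 cluster spikes for isolation distance")
    if len(N) < n:
        warnings.warn("fewer noise spikes than cluster spikes; "
                      "isolation distance unbounded", stacklevel=2)
        return float("inf")
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular cluster covariance; ridge-regularised",
                      stacklevel=2)
        eps = ridge_frac * float(np.mean(np.diag(cov)))
        inv = np.linalg.inv(cov + max(eps, 1e-12) * np.eye(cov.shape[0]))
    d = N - mu
    md2 = np.einsum("ij,jk,ik->i", d, inv, d)
    md2_sorted = np.sort(md2)
    return float(md2_sorted[n - 1])


def classify_unit(qc: UnitQC) -> UnitQC:
    """Apply exclusion rules, then label surviving units pyramidal/other."""
    excluded = (
        qc.isi_violation_frac > MAX_ISI_VIOLATION_FRAC
        or qc.n_spikes < MIN_SPIKES
        or qc.isolation_distance < MIN_ISOLATION_DISTANCE
    )
    qc.status = "excluded" if excluded else "included"
    if qc.status == "included" and qc.width_us > PYRAMIDAL_MIN_WIDTH_US \
            and qc.csi >= PYRAMIDAL_MIN_CSI:
        qc.cell_class = "pyramidal"
    else:
        qc.cell_class = "other"
    return qc
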