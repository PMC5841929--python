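"""Population-vector (PV) analysis of ensemble spatial coding.

A population vector is the set of firing rates of all place cells at one
spatial bin. Left- and right-direction rate curves are stacked along the
bin axis and every bin pair is correlated with Spearman's rho, giving a
(2*bins) x (2*bins) matrix whose quadrants separate same-direction
(left-left, right-right) from opposite-direction (left-right) coding.
Distance-averaged profiles summarise how correlation falls off with
track separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DataError


@dataclass
class PopulationMatrix:
    pv: np.ndarray              # (2*bins, cells): left block then right block
    corr: np.ndarray            # Spearman matrix, NaN-masked where undefined
    n_bins: int                 # bins per direction

    def quadrant(self, name: str) -> np.ndarray:
        """Sub-matrix by quadrant: 'LL', 'RR' (same direction) or
        'LR', 'RL' (opposite)."""
        n = self.n_bins
        sl = {"L": slice(0, n), "R": slice(n, 2 * n)}
        return self.corr[sl[name[0]], sl[name[1]]]


@dataclass
class DistanceProfile:
    distance_cm: np.ndarray
    mean_corr: np.ndarray
    sem_corr: np.ndarray
    entries: list               # list of 1D arrays, one per distance
    quadrant_set: str           # "same" | "opposite"


def build_population_vectors(curves: list, bin_cm: float = 1.0) -> np.ndarray:
    """Stack per-cell (left, right) rate curves into the PV matrix.

    ``curves`` is a list of (left_rate, right_rate) arrays sharing one
    binning; cells become columns. Left and right laps are treated
    separately: rows 0..bins-1 are left bins, rows bins..2*bins-1 right.
    """
    if not curves:
        raise DataError("no cells")
    n_bins = len(np.asarray(curves[0][0]))
    cols = []
    for left, right in curves:
        left = np.asarray(left, dtype=float)
        right = np.asarray(right, dtype=float)
        if len(left) != n_bins or len(right) != n_bins:
            raise DataError("rate curves have mismatched binning")
        cols.append(np.concatenate([left, right]))
    return np.column_stack(cols)


def pv_correlation_matrix(pv: np.ndarray) -> PopulationMatrix:
    """Pairwise Spearman correlation between all spatial-bin PVs.

    Rows with any missing rate or zero variance across cells yield NaN
    (masked) correlations.
    """
    pv = np.asarray(pv, dtype=float)
    if pv.shape[1] < 2:
        raise DataError("need >=2 cells for PV correlation")
    n_rows = pv.shape[0]
    valid = np.isfinite(pv).all(axis=1)
    valid[valid] &= pv[valid].std(axis=1) > 0
    corr = np.full((n_rows, n_rows), np.nan)
    idx = np.flatnonzero(valid)
    if len(idx) >= 2:
        ranks = np.apply_along_axis(stats.rankdata, 1, pv[idx])
        c = np.corrcoef(ranks)
        corr[np.ix_(idx, idx)] = c
    # a bin correlates perfectly with itself whenever defined
    corr[idx, idx] = 1.0
    return PopulationMatrix(pv, corr, n_rows // 2)


def distance_profile(pm: PopulationMatrix, quadrant_set: str = "same",
                     bin_cm: float = 1.0) -> DistanceProfile:
    """Mean +/- SEM correlation as a function of track distance.

    Same-direction profiles pool the LL and RR quadrants by absolute bin
    separation; opposite-direction profiles use the LR quadrant with the
    *signed* offset (right position minus left position) retained so any
    asymmetric peak shift stays visible.
    """
    n = pm.n_bins
    if quadrant_set == "same":
        dists = np.arange(0, n)
        entries = [[] for _ in dists]
        for q in ("LL", "RR"):
            m = pm.quadrant(q)
            for i in range(n):
                for j in range(i, n):
                    v = m[i, j]
                    if np.isfinite(v):
                        entries[j - i].append(v)
    elif quadrant_set == "opposite":
        dists = np.arange(-(n - 1), n)
        entries = [[] for _ in dists]
        m = pm.quadrant("LR")
        for i in range(n):          # left-bin position
            for j in range(n):      # right-bin position
                v = m[i, j]
                if np.isfinite(v):
                    entries[(j - i) + (n - 1)].append(v)
    else:
        raise DataError("quadrant_set must be 'same' or 'opposite'")

    mean = np.array([np.mean(e) if e else np.nan for e in entries])
    sem = np.array([np.std(e, ddof=1) / np.sqrt(len(e)) if len(e) > 1
                    else np.nan for e in entries])
    return DistanceProfile(dists * bin_cm, mean, sem,
                           [np.asarray(e) for e in entries], quadrant_set)


def compare_profiles(a: DistanceProfile, b: DistanceProfile) -> list:
    """Two-sided rank-sum test on correlation entries per distance bin.

    Returns one ``(distance_cm, statistic, p)`` tuple per distance where
    both profiles have entries; empty bins are skipped.
    """
    if len(a.distance_cm) != len(b.distance_cm) or \
            not np.allclose(a.distance_cm, b.distance_cm):
        raise DataError("profiles must share a distance grid")
    out = []
    for d, ea, eb in zip(a.distance_cm, a.entries, b.entries):
        if len(ea) == 0 or len(eb) == 0:
            continue
        if np.ptp(np.concatenate([ea, eb])) == 0:
            out.append((float(d), float("nan"), 1.0))
            continue
        res = stats.mannwhitneyu(ea, eb, alternative="two-sided")
        out.append((float(d), float(res.statistic), float(res.pvalue)))
    return out
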