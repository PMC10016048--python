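"""Stride segmentation and DTW-based stride-to-stride variability.

A gait cycle is the interval between two consecutive heel strikes of the
same foot; heel strikes are the local maxima of the fore-aft (Z) heel
position with topographic prominence above 0.1 m.  Cycles are resampled to
100 samples, screened for outlying kurtosis, and compared stride-to-stride
with classical dynamic time warping on the 3D Euclidean local cost.  The
per-participant variability measure is the mean DTW distance over all
consecutive-stride comparisons, pooled across feet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import kurtosis

from .errors import DegenerateSetError, EmptySampleError, InvalidConfigError, TooShortError
from .synthetic import GaitTrace

__all__ = [
    "GaitCycle",
    "GaitSummary",
    "detect_heel_strikes",
    "segment_cycles",
    "reject_outlier_cycles",
    "resample_cycle",
    "dtw_distance",
    "mean_dtw",
    "analyze_gait",
]

MIN_PROMINENCE_M = 0.1
RESAMPLE_N = 100
KURTOSIS_K_SD = 5.0

try:  # numba accelerates the O(mn) DP; the pure-python path is equivalent
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class GaitCycle:
    """One stride: raw heel trajectory between consecutive strikes."""

    foot: str
    start_idx: int
    end_idx: int  # exclusive
    trajectory: np.ndarray  # (n, 3), meters


@dataclass
class GaitSummary:
    participant_id: str
    cognitive_load: str  # ST | DT
    n_cycles_kept: int
    n_cycles_rejected: int
    mean_dtw_m: float


def detect_heel_strikes(z: np.ndarray, min_prominence_m: float = MIN_PROMINENCE_M) -> np.ndarray:
    """Indices of Z-waveform local maxima with prominence above the cutoff."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or len(z) < 3:
        raise TooShortError("need a 1D series of length >= 3")
    peaks, _ = find_peaks(z, prominence=min_prominence_m)
    return peaks


def segment_cycles(trace: GaitTrace, strikes: np.ndarray) -> list[GaitCycle]:
    """One cycle per consecutive strike pair, covering [strike_k, strike_{k+1})."""
    strikes = np.asarray(strikes, dtype=int)
    if len(strikes) < 2:
        raise TooShortError("need at least 2 heel strikes to form a cycle")
    return [
        GaitCycle(
            foot=trace.foot,
            start_idx=int(s0),
            end_idx=int(s1),
            trajectory=trace.xyz[s0:s1],
        )
        for s0, s1 in zip(strikes[:-1], strikes[1:])
    ]


def _cycle_kurtosis(cycle: GaitCycle) -> float:
    """Max over the three axes of the per-axis (Pearson) sample kurtosis."""
    return float(np.max(kurtosis(cycle.trajectory, axis=0, fisher=False, bias=True)))


def reject_outlier_cycles(
    cycles: list[GaitCycle], k_sd: float = KURTOSIS_K_SD
) -> tuple[list[GaitCycle], list[GaitCycle]]:
    """Screen cycles whose kurtosis deviates more than ``k_sd`` SD from the mean.

    The kurtosis statistic is the max across the three coordinate axes; mean
    and SD are taken over the full cycle set handed in (both feet of one
    participant-condition pooled).  Zero SD keeps everything.  Returns
    ``(kept, rejected)``.
    """
    if len(cycles) < 3:
        raise TooShortError("need >= 3 cycles for a meaningful mean/SD")
    stat = np.array([_cycle_kurtosis(c) for c in cycles])
    sd = stat.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        return list(cycles), []
    keep = np.abs(stat - stat.mean()) <= k_sd * sd
    kept = [c for c, k in zip(cycles, keep) if k]
    rejected = [c for c, k in zip(cycles, keep) if not k]
    if not kept:
        raise DegenerateSetError("all cycles rejected by the kurtosis screen")
    return kept, rejected


def resample_cycle(trajectory: np.ndarray, n: int = RESAMPLE_N) -> np.ndarray:
    """Linear interpolation of each coordinate onto ``n`` even phase points."""
    if n < 2:
        raise InvalidConfigError("resampling length must be >= 2")
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[0] < 2:
        raise TooShortError("cycle must have >= 2 samples")
    old = np.linspace(0.0, 1.0, traj.shape[0])
    new = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(new, old, traj[:, d]) for d in range(traj.shape[1])])


def _dtw_python(a: np.ndarray, b: np.ndarray) -> float:
    m, n = len(a), len(b)
    inf = np.inf
    dp = np.full((m + 1, n + 1), inf)
    dp[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d = np.sqrt(((a[i - 1] - b[j - 1]) ** 2).sum())
            dp[i, j] = d + min(dp[i - 1, j], dp[i, j - 1], dp[i - 1, j - 1])
    return float(dp[m, n])


if _HAVE_NUMBA:

    @njit(cache=True)
    def _dtw_numba(a, b):  # pragma: no cover - exercised via dtw_distance
        m, n = a.shape[0], b.shape[0]
        dp = np.empty((m + 1, n + 1))
        dp[:, :] = np.inf
        dp[0, 0] = 0.0
        for i in range(1, m + 1):
            for j in range(1, n + 1):
                d = 0.0
                for k in range(3):
                    diff = a[i - 1, k] - b[j - 1, k]
                    d += diff * diff
                d = np.sqrt(d)
                prev = dp[i - 1, j]
                if dp[i, j - 1] < prev:
                    prev = dp[i, j - 1]
                if dp[i - 1, j - 1] < prev:
                    prev = dp[i - 1, j - 1]
                dp[i, j] = d + prev
        return dp[m, n]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classical DTW distance between two 3D trajectories, meters.

    Local cost is the 3D Euclidean distance between position samples;
    symmetric match/insert/delete steps, boundary-anchored, no warping
    window, no path-length normalisation (the summed cost is returned).
    """
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 3 or b.shape[1] != 3:
        raise InvalidConfigError("trajectories must be (n, 3) arrays")
    if len(a) < 1 or len(b) < 1:
        raise TooShortError("trajectories must be non-empty")
    if _HAVE_NUMBA:
        return float(_dtw_numba(a, b))
    return _dtw_python(a, b)


def consecutive_dtw(cycles: list[np.ndarray]) -> list[float]:
    """DTW distances between each stride and the next (within one foot)."""
    return [dtw_distance(cycles[i], cycles[i + 1]) for i in range(len(cycles) - 1)]


def mean_dtw(
    cycles_left: list[np.ndarray], cycles_right: list[np.ndarray]
) -> tuple[float, list[float]]:
    """Mean of pooled left- and right-foot consecutive-stride DTW distances."""
    dists = consecutive_dtw(cycles_left) + consecutive_dtw(cycles_right)
    if not dists:
        raise EmptySampleError("no consecutive stride pair on either foot")
    return float(np.mean(dists)), dists


def analyze_gait(
    left: GaitTrace,
    right: GaitTrace,
    participant_id: str = "",
    cognitive_load: str = "ST",
    min_prominence_m: float = MIN_PROMINENCE_M,
    resample_n: int = RESAMPLE_N,
    k_sd: float = KURTOSIS_K_SD,
) -> GaitSummary:
    """Full per-participant-condition gait analysis.

    Strikes -> cycles per foot -> pooled kurtosis screen -> 100-sample
    resampling -> consecutive-stride DTW within foot -> pooled mean.
    Cycles removed by the screen create a new adjacency between their
    neighbours.
    """
    per_foot: dict[str, list[GaitCycle]] = {}
    for trace in (left, right):
        strikes = detect_heel_strikes(trace.xyz[:, 2], min_prominence_m)
        per_foot[trace.foot] = segment_cycles(trace, strikes)
    pooled = per_foot[left.foot] + per_foot[right.foot]
    kept, rejected = reject_outlier_cycles(pooled, k_sd)
    kept_ids = {id(c) for c in kept}
    resampled = {
        foot: [resample_cycle(c.trajectory, resample_n) for c in cyc if id(c) in kept_ids]
        for foot, cyc in per_foot.items()
    }
    mean_m, _ = mean_dtw(resampled[left.foot], resampled[right.foot])
    return GaitSummary(
        participant_id=participant_id,
        cognitive_load=cognitive_load,
        n_cycles_kept=len(kept),
        n_cycles_rejected=len(rejected),
        mean_dtw_m=mean_m,
    )
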