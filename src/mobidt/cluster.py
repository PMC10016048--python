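"""Spatiotemporal cluster statistics on walking-minus-sitting ERP differences.

Pointwise one-sample t-maps over participants, cluster formation on an
electrode-neighbourhood graph (neighbouring electrodes at the same timepoint,
same electrode at consecutive timepoints), the weighted cluster mass
statistic sum(|t| - t_thresh)^w over members, and Monte-Carlo inference by
participant-level sign flips (the exchangeability implied by the paired
design after within-subject differencing).  Positive and negative clusters
are formed separately and tail probabilities are doubled for the two-sided
test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

from .errors import InvalidConfigError
from .montage import angular_distance

__all__ = [
    "build_adjacency",
    "pointwise_t",
    "form_clusters",
    "cluster_permutation_test",
    "Cluster",
    "ClusterResult",
    "DEFAULT_NEIGHBOR_RADIUS_RAD",
]

logger = logging.getLogger(__name__)

# Great-circle neighbour radius on the unit head sphere.  Chosen so the
# 64-channel montage averages ~6-8 neighbours per electrode, the usual
# density of toolbox neighbourhood templates.
DEFAULT_NEIGHBOR_RADIUS_RAD = 0.55

T_SENTINEL = 1e6  # replaces +-inf t-values from zero-variance cells


def build_adjacency(positions: np.ndarray, max_dist: float = DEFAULT_NEIGHBOR_RADIUS_RAD) -> np.ndarray:
    """Boolean electrode-neighbour matrix from unit-sphere positions.

    Electrodes within great-circle distance ``max_dist`` (radians) are
    neighbours.  Symmetric, zero diagonal.  Isolated electrodes are retained
    (they can still form singleton or purely temporal clusters) but logged.
    """
    pos = np.asarray(positions, dtype=float)
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    adj = angular_distance(pos) <= max_dist
    np.fill_diagonal(adj, False)
    isolated = np.flatnonzero(adj.sum(axis=1) == 0)
    if isolated.size:
        logger.warning("isolated electrodes at radius %.3f: %s", max_dist, isolated.tolist())
    return adj


def pointwise_t(diffs: np.ndarray) -> np.ndarray:
    """One-sample t against zero per (channel, time); df = n_participants - 1.

    Zero-variance cells would give +-inf; they are guarded to a large finite
    sentinel carrying the sign of the mean (zero mean gives t = 0).
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 3:
        raise InvalidConfigError("expected participants x channels x time")
    n = diffs.shape[0]
    if n < 3:
        raise InvalidConfigError("need >= 3 participants for a t-map")
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("zero-variance cells in t-map: %d", int(zero_var.sum()))
        t[zero_var] = np.sign(mean[zero_var]) * T_SENTINEL
    return t


@dataclass
class Cluster:
    sign: int  # +1 or -1
    members: np.ndarray  # (k, 2) array of (channel, time) indices
    mass: float
    p_perm: float = np.nan


@dataclass
class ClusterResult:
    t_map: np.ndarray
    t_thresh: float
    clusters: list[Cluster]
    n_permutations: int
    alpha: float
    seed: int | None = None
    null_max_pos: np.ndarray | None = None
    null_max_neg: np.ndarray | None = None

    def min_p(self) -> float:
        """Smallest cluster p-value, or NaN when no cluster formed."""
        return min((c.p_perm for c in self.clusters), default=np.nan)

    def significant(self, alpha: float | None = None) -> list[Cluster]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p_perm <= a]

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": i,
                "sign": c.sign,
                "n_members": len(c.members),
                "mass": c.mass,
                "p_perm": c.p_perm,
                "t_start": int(c.members[:, 1].min()),
                "t_end": int(c.members[:, 1].max()),
                "n_channels": len(np.unique(c.members[:, 0])),
            }
            for i, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "cluster", "sign", "n_members", "mass", "p_perm",
                "t_start", "t_end", "n_channels",
            ],
        )

    def to_dict(self) -> dict:
        return {
            "t_thresh": float(self.t_thresh),
            "n_permutations": int(self.n_permutations),
            "alpha": float(self.alpha),
            "clusters": [
                {
                    "sign": int(c.sign),
                    "mass": float(c.mass),
                    "p_perm": float(c.p_perm),
                    "members": [[int(a), int(b)] for a, b in c.members],
                }
                for c in self.clusters
            ],
        }


def _adjacency_pairs(adjacency: np.ndarray) -> np.ndarray:
    i, j = np.nonzero(np.triu(adjacency, k=1))
    return np.column_stack([i, j])


def _label_components(mask: np.ndarray, pairs: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    """Connected components of the supra-threshold (channel, time) graph.

    Links: same electrode at consecutive timepoints, neighbouring electrodes
    at the same timepoint.  Returns (labels over supra nodes, n_components,
    linear indices of supra nodes).
    """
    n_ch, n_t = mask.shape
    supra = np.flatnonzero(mask.ravel())
    if supra.size == 0:
        return np.empty(0, dtype=int), 0, supra
    compact = -np.ones(n_ch * n_t, dtype=int)
    compact[supra] = np.arange(supra.size)

    edges_u, edges_v = [], []
    tmp = mask[:, :-1] & mask[:, 1:]
    ch, tt = np.nonzero(tmp)
    if ch.size:
        edges_u.append(ch * n_t + tt)
        edges_v.append(ch * n_t + tt + 1)
    if pairs.size:
        both = mask[pairs[:, 0]] & mask[pairs[:, 1]]  # (n_pairs, n_t)
        pi, tt = np.nonzero(both)
        if pi.size:
            edges_u.append(pairs[pi, 0] * n_t + tt)
            edges_v.append(pairs[pi, 1] * n_t + tt)
    if edges_u:
        u = compact[np.concatenate(edges_u)]
        v = compact[np.concatenate(edges_v)]
        g = sparse.csr_matrix(
            (np.ones(len(u), dtype=np.int8), (u, v)), shape=(supra.size, supra.size)
        )
        n_comp, labels = connected_components(g, directed=False)
    else:
        n_comp, labels = supra.size, np.arange(supra.size)
    return labels, n_comp, supra


def _clusters_one_sign(
    t_map: np.ndarray, pairs: np.ndarray, t_thresh: float, weight: float, sign: int
) -> list[Cluster]:
    mask = (sign * t_map) > t_thresh
    labels, n_comp, supra = _label_components(mask, pairs)
    if n_comp == 0:
        return []
    n_t = t_map.shape[1]
    exceed = (np.abs(t_map.ravel()[supra]) - t_thresh) ** weight
    masses = np.bincount(labels, weights=exceed, minlength=n_comp)
    clusters = []
    for lab in range(n_comp):
        nodes = supra[labels == lab]
        members = np.column_stack([nodes // n_t, nodes % n_t])
        clusters.append(Cluster(sign=sign, members=members, mass=float(masses[lab])))
    return clusters


def form_clusters(
    t_map: np.ndarray,
    adjacency: np.ndarray,
    t_thresh: float,
    wcm_weight: float = 1.0,
) -> list[Cluster]:
    """Sign-homogeneous supra-threshold clusters with weighted masses.

    Mass = sum over members of (|t| - t_thresh)^wcm_weight; weight 1 is the
    plain exceedance-mass statistic.
    """
    if t_thresh <= 0:
        raise InvalidConfigError("t_thresh must be positive")
    t_map = np.asarray(t_map, dtype=float)
    pairs = _adjacency_pairs(np.asarray(adjacency, dtype=bool))
    out = _clusters_one_sign(t_map, pairs, t_thresh, wcm_weight, +1)
    out += _clusters_one_sign(t_map, pairs, t_thresh, wcm_weight, -1)
    return out


def _max_masses(
    t_row: np.ndarray, pairs: np.ndarray, t_thresh: float, weight: float
) -> tuple[float, float]:
    out = []
    for sign in (+1, -1):
        mask = (sign * t_row) > t_thresh
        labels, n_comp, supra = _label_components(mask, pairs)
        if n_comp == 0:
            out.append(0.0)
            continue
        exceed = (np.abs(t_row.ravel()[supra]) - t_thresh) ** weight
        out.append(float(np.bincount(labels, weights=exceed, minlength=n_comp).max()))
    return out[0], out[1]


def cluster_permutation_test(
    diffs: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int = 5000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    wcm_weight: float = 1.0,
    seed=None,
    chunk: int = 256,
) -> ClusterResult:
    """Cluster-based permutation test on difference waveforms.

    The cluster-forming threshold is the parametric two-tailed t quantile at
    ``cluster_alpha`` with df = n - 1.  The null is built by random sign
    flips of whole participants; the maximum cluster mass per sign is
    recorded per permutation.  Cluster p = (1 + #{null max >= observed}) /
    (1 + n_perm), doubled for the two-sided correction and capped at 1.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 3 or diffs.shape[0] < 5:
        raise InvalidConfigError("need participants x channels x time with n >= 5")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives coarse p-values", stacklevel=2)
    n, n_ch, n_t = diffs.shape
    t_thresh = float(t_dist.ppf(1 - cluster_alpha / 2.0, df=n - 1))
    t_obs = pointwise_t(diffs)
    pairs = _adjacency_pairs(np.asarray(adjacency, dtype=bool))
    clusters = form_clusters(t_obs, adjacency, t_thresh, wcm_weight)

    rng = np.random.default_rng(seed)
    flat = diffs.reshape(n, -1)
    ssq = (flat ** 2).sum(axis=0)  # invariant under sign flips
    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        flips = rng.choice([-1.0, 1.0], size=(k, n))
        mean = (flips @ flat) / n
        var = (ssq[None, :] - n * mean ** 2) / (n - 1)
        var = np.maximum(var, 1e-300)
        t_null = mean / np.sqrt(var / n)
        for r in range(k):
            mp, mn = _max_masses(t_null[r].reshape(n_ch, n_t), pairs, t_thresh, wcm_weight)
            null_pos[done + r] = mp
            null_neg[done + r] = mn
        done += k

    for c in clusters:
        null = null_pos if c.sign > 0 else null_neg
        p_one = (1.0 + float((null >= c.mass).sum())) / (1.0 + n_perm)
        c.p_perm = min(1.0, 2.0 * p_one)

    return ClusterResult(
        t_map=t_obs,
        t_thresh=t_thresh,
        clusters=clusters,
        n_permutations=n_perm,
        alpha=alpha,
        seed=seed if isinstance(seed, int) else None,
        null_max_pos=null_pos,
        null_max_neg=null_neg,
    )


def plot_clusterplot(result: ClusterResult, times_ms=None, ch_names=None, ax=None):
    """Channels x time t-map heat map with significant clusters outlined."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    extent = None
    if times_ms is not None:
        extent = [times_ms[0], times_ms[-1], result.t_map.shape[0], 0]
    vmax = np.percentile(np.abs(result.t_map), 99)
    im = ax.imshow(result.t_map, aspect="auto", cmap="RdYlBu_r", vmin=-vmax, vmax=vmax,
                   extent=extent, interpolation="nearest")
    for c in result.significant():
        tcol = c.members[:, 1]
        if times_ms is not None:
            tcol = np.asarray(times_ms)[tcol]
        ax.scatter(tcol, c.members[:, 0] + 0.5, s=1, c="k", alpha=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("electrode")
    if ch_names is not None:
        ax.set_yticks(np.arange(len(ch_names)) + 0.5)
        ax.set_yticklabels(ch_names, fontsize=4)
    plt.colorbar(im, ax=ax, label="t")
    return ax
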