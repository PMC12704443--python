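"""Nonparametric cluster-based permutation tests on channel x axis grids.

Works on paired designs (participant x channel x time, or x frequency):
pointwise dependent-samples t statistics are thresholded at two-tailed
p < .05, suprathreshold points of equal sign are merged into clusters that
are connected under channel adjacency OR along-axis adjacency, each
cluster's statistic is its summed t, and significance comes from the null
distribution of the maximum |cluster sum| over sign-flip permutations of
the within-participant differences.  A cluster is significant at p < .025
per tail (two-sided .05 familywise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

CLUSTER_ALPHA = 0.025        # per-tail cluster significance
POINT_ALPHA = 0.05           # two-tailed pointwise threshold


def adjacency_from_positions(pos: np.ndarray, scale: float = 1.5) -> np.ndarray:
    """Channel neighbor graph from sensor positions.

    Channels closer than ``scale`` times the median nearest-neighbor
    distance are neighbors.  Symmetric, irreflexive.
    """
    pos = np.asarray(pos, dtype=float)
    n = pos.shape[0]
    if n == 1:
        return np.zeros((1, 1), dtype=bool)
    d = squareform(pdist(pos))
    np.fill_diagonal(d, np.inf)
    thresh = scale * np.median(d.min(axis=1))
    adj = d <= thresh
    np.fill_diagonal(adj, False)
    return adj | adj.T


@dataclass
class Cluster:
    points: np.ndarray          # (m, 2) array of (channel, axis) indices
    stat: float                 # summed t
    sign: int
    p: float = np.nan


@dataclass
class ClusterResult:
    clusters: list
    null_max: np.ndarray
    n_perm: int
    t_obs: np.ndarray
    df: int

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.p < CLUSTER_ALPHA]


def paired_t_map(cond_a: np.ndarray, cond_b: np.ndarray) -> np.ndarray:
    """Pointwise dependent-samples t over the participant axis.

    Points with zero-variance differences get t = 0 (flagged in the log).
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have the same shape")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants for a paired t map")
    d = a - b
    return _t_from_diffs(d)


def _t_from_diffs(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    if not ok.all():
        logger.info("%d zero-variance points set to t=0", int((~ok).sum()))
    return t


def clusterize(
    t_map: np.ndarray,
    df: int,
    adjacency: np.ndarray,
    point_alpha: float = POINT_ALPHA,
) -> list:
    """Signed suprathreshold clusters of a channel x axis t map.

    Two suprathreshold points are connected when they share a channel and
    are consecutive along the axis, or share an axis position on neighboring
    channels; clusters never mix signs.
    """
    n_ch, n_ax = t_map.shape
    if adjacency.shape != (n_ch, n_ch):
        raise ValueError("adjacency must be n_channels x n_channels")
    thr = stats.t.ppf(1.0 - point_alpha / 2.0, df)
    out = []
    for sign in (+1, -1):
        mask = sign * t_map > thr
        labels = _connected_components(mask, adjacency)
        for lab in range(labels.max() + 1 if labels.size else 0):
            pts = np.argwhere(labels == lab)
            if pts.size == 0:
                continue
            s = float(t_map[pts[:, 0], pts[:, 1]].sum())
            out.append(Cluster(points=pts, stat=s, sign=sign))
    return out


def _connected_components(mask: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Label connected components of a boolean channel x axis mask.

    Returns an int array, -1 outside the mask.  Iterative label propagation:
    along the axis within channels, then across neighboring channels at the
    same axis position, until stable.
    """
    n_ch, n_ax = mask.shape
    labels = np.full((n_ch, n_ax), -1, dtype=int)
    idx = np.argwhere(mask)
    if idx.size == 0:
        return labels
    # union-find over suprathreshold points
    flat = {tuple(p): i for i, p in enumerate(idx)}
    parent = np.arange(len(idx))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    neighbors = [np.flatnonzero(adjacency[c]) for c in range(n_ch)]
    for i, (c, a) in enumerate(idx):
        if a + 1 < n_ax and mask[c, a + 1]:
            union(i, flat[(c, a + 1)])
        for c2 in neighbors[c]:
            if mask[c2, a]:
                union(i, flat[(c2, a)])
    roots = np.array([find(i) for i in range(len(idx))])
    _, renum = np.unique(roots, return_inverse=True)
    labels[idx[:, 0], idx[:, 1]] = renum
    return labels


def membership_frame(result: "ClusterResult"):
    """Cluster membership as a tidy table (cluster_id, sign, p, channel,
    axis_index) for TSV export."""
    import pandas as pd

    rows = []
    for i, c in enumerate(result.clusters):
        for ch, ax in c.points:
            rows.append(dict(cluster_id=i, sign=c.sign, p=c.p,
                             channel=int(ch), axis_index=int(ax)))
    return pd.DataFrame(rows, columns=["cluster_id", "sign", "p", "channel",
                                       "axis_index"])


def _max_cluster_stat(t_map, df, adjacency, point_alpha) -> float:
    cl = clusterize(t_map, df, adjacency, point_alpha)
    return max((abs(c.stat) for c in cl), default=0.0)


def permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    point_alpha: float = POINT_ALPHA,
) -> ClusterResult:
    """Cluster permutation test for a paired design.

    The exchangeability unit is the participant: each permutation flips the
    sign of each participant's condition difference (equivalently, swaps the
    condition labels within the participant).  Cluster p-values use the
    add-one rule p = (1 + #{null >= |obs|}) / (1 + n_perm).
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    d = a - b
    n = d.shape[0]
    df = n - 1
    if n < 3:
        raise ValueError("need at least 3 participants")
    if 2 ** n < n_perm:
        logger.warning("only %d distinct sign flips for %d requested permutations",
                       2 ** n, n_perm)
    t_obs = _t_from_diffs(d)
    clusters = clusterize(t_obs, df, adjacency, point_alpha)

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
    # vectorized permuted t maps: the per-point sum of squares is invariant
    # under sign flips, only the mean changes
    shp = d.shape[1:]
    df_flat = d.reshape(n, -1)
    ss = (df_flat ** 2).sum(axis=0)
    means = (flips @ df_flat) / n                       # n_perm x points
    var = np.maximum(ss[None, :] - n * means ** 2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(var > 0, means / np.sqrt(var / n), 0.0)

    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _max_cluster_stat(t_perm[i].reshape(shp), df, adjacency, point_alpha)

    for c in clusters:
        c.p = (1.0 + float((null >= abs(c.stat)).sum())) / (1.0 + n_perm)
    return ClusterResult(clusters=clusters, null_max=null, n_perm=n_perm,
                         t_obs=t_obs, df=df)
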