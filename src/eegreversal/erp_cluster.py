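"""Univariate ERP contrasts with spatiotemporal cluster-based permutation.

Per participant, condition-mean ERPs are contrasted (photograph vs.
drawing, or animate vs. inanimate); a paired t statistic across
participants is computed per channel × timepoint. Points exceeding the
cluster-forming threshold are grouped by spatiotemporal adjacency —
neighbouring timepoints on the same channel, or spatially neighbouring
channels at the same timepoint — after discarding points supported by
fewer than two suprathreshold neighbouring channels. Each cluster is
scored by the sum of its member t values and compared against the Monte
Carlo distribution of the maximal cluster statistic under random
within-participant condition relabelling (a paired design, so a sign flip
of each participant's difference map).

For response-locked retrieval data the full −3000…+100 ms window is
subdivided into 300 ms sub-epochs, each tested (and corrected) separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.spatial import Delaunay, distance_matrix

from .containers import EpochSet, label_vector

logger = logging.getLogger(__name__)


class ErpError(ValueError):
    pass


@dataclass
class TStatMap:
    t: np.ndarray  # (n_channels, n_times)
    times: np.ndarray
    channel_labels: list
    n_participants: int
    contrast: str


@dataclass
class ChannelNeighbourhood:
    """Symmetric channel adjacency without self-neighbours."""

    adjacency: sparse.csr_matrix
    channel_labels: list

    def __post_init__(self) -> None:
        a = self.adjacency
        if (a != a.T).nnz != 0:
            raise ErpError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ErpError("adjacency must have no self-neighbours")

    @classmethod
    def from_positions(
        cls, positions: np.ndarray, channel_labels: list, distance_factor: float = 1.5
    ) -> "ChannelNeighbourhood":
        """Delaunay neighbours of the 2-D layout, pruned by edge length.

        Edges longer than ``distance_factor`` × the median Delaunay edge
        length are discarded, which prevents spurious long-range links
        across the layout hull.
        """
        positions = np.asarray(positions, dtype=float)
        n = positions.shape[0]
        if n < 2:
            raise ErpError("neighbourhood needs at least 2 channels")
        if n <= 3:
            adj = np.ones((n, n), dtype=bool) & ~np.eye(n, dtype=bool)
            return cls(sparse.csr_matrix(adj), list(channel_labels))
        tri = Delaunay(positions)
        edges = set()
        for simplex in tri.simplices:
            for i in range(3):
                a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
                edges.add((a, b))
        dists = distance_matrix(positions, positions)
        lengths = np.array([dists[a, b] for a, b in edges])
        cutoff = distance_factor * np.median(lengths)
        rows, cols = [], []
        for a, b in edges:
            if dists[a, b] <= cutoff:
                rows += [a, b]
                cols += [b, a]
        adj = sparse.csr_matrix(
            (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n, n)
        )
        return cls(adj, list(channel_labels))


@dataclass
class ClusterResult:
    """One spatiotemporal cluster with its Monte Carlo corrected p value."""

    mask: np.ndarray = field(repr=False)  # (n_channels, n_times) membership
    statistic: float  # sum of member t values
    sign: int
    p_value: float
    times: np.ndarray = field(repr=False)
    channel_labels: list = field(repr=False)
    extent_ms: tuple = (np.nan, np.nan)
    peak_time_ms: float = np.nan
    sub_epoch: tuple | None = None

    @property
    def channels(self) -> np.ndarray:
        return np.flatnonzero(self.mask.any(axis=1))


# ---------------------------------------------------------------------------
# participant-level contrast maps and t statistics
# ---------------------------------------------------------------------------

def participant_difference_maps(
    epochs: EpochSet, contrast: str, window: tuple
) -> tuple:
    """Per-participant condition-mean ERP differences, shape (P, C, Tw).

    The difference is level1 − level0 of the contrast factor (drawing −
    photograph, or inanimate − animate). Participants missing a condition
    are dropped with a warning.
    """
    idx = epochs.time_indices(window)
    diffs, kept = [], []
    for pid, sub in epochs.per_participant():
        y = label_vector(sub.trials, contrast)
        if y.min() == y.max():
            logger.warning("participant %s misses a %s condition; dropped", pid, contrast)
            continue
        block = sub.data[:, :, idx]
        diffs.append(block[y == 1].mean(axis=0) - block[y == 0].mean(axis=0))
        kept.append(pid)
    if len(diffs) < 2:
        raise ErpError("need at least 2 participants with both conditions")
    return np.stack(diffs), epochs.times[idx], kept


def _tmap(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def condition_tstats(epochs: EpochSet, contrast: str, window: tuple) -> TStatMap:
    """Across-participant paired t statistics per channel × timepoint."""
    diffs, times, kept = participant_difference_maps(epochs, contrast, window)
    return TStatMap(
        t=_tmap(diffs),
        times=times,
        channel_labels=epochs.channel_labels,
        n_participants=len(kept),
        contrast=contrast,
    )


# ---------------------------------------------------------------------------
# clustering machinery
# ---------------------------------------------------------------------------

def _min_neighbour_filter(
    mask: np.ndarray, adjacency: sparse.csr_matrix, min_neighbours: int
) -> np.ndarray:
    """Drop suprathreshold points with too few suprathreshold neighbours.

    A point survives only if at least ``min_neighbours`` spatially
    adjacent channels are also suprathreshold (same sign) at the same
    timepoint; an effect confined to a single isolated channel can
    therefore never form a cluster.
    """
    if min_neighbours <= 0:
        return mask
    counts = adjacency.astype(np.int32) @ mask.astype(np.int32)
    return mask & (counts >= min_neighbours)


def _clusters_from_mask(
    mask: np.ndarray, tmap: np.ndarray, adjacency: sparse.csr_matrix
):
    """Connected components of a suprathreshold mask; yields (member_mask, stat)."""
    n_ch, n_t = mask.shape
    nodes = np.flatnonzero(mask.ravel())
    if nodes.size == 0:
        return []
    pos = -np.ones(n_ch * n_t, dtype=int)
    pos[nodes] = np.arange(nodes.size)
    ch, tt = np.unravel_index(nodes, (n_ch, n_t))
    rows, cols = [], []
    # temporal adjacency: same channel, consecutive timepoints
    flat_next = nodes + 1
    ok = (tt < n_t - 1) & (pos[np.minimum(flat_next, n_ch * n_t - 1)] >= 0)
    rows.append(pos[nodes[ok]])
    cols.append(pos[nodes[ok] + 1])
    # spatial adjacency: neighbouring channels, same timepoint
    adj = adjacency.tocoo()
    for a, b in zip(adj.row, adj.col):
        if a < b:
            both = mask[a] & mask[b]
            ts = np.flatnonzero(both)
            if ts.size:
                rows.append(pos[a * n_t + ts])
                cols.append(pos[b * n_t + ts])
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
    graph = sparse.csr_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(nodes.size, nodes.size)
    )
    n_comp, labels = sparse.csgraph.connected_components(graph, directed=False)
    out = []
    for comp in range(n_comp):
        members = nodes[labels == comp]
        member_mask = np.zeros(n_ch * n_t, dtype=bool)
        member_mask[members] = True
        member_mask = member_mask.reshape(n_ch, n_t)
        out.append((member_mask, float(tmap[member_mask].sum())))
    return out


def _max_cluster_stat(tmap, t_crit, adjacency, min_neighbours) -> float:
    best = 0.0
    for sign in (1, -1):
        mask = _min_neighbour_filter(sign * tmap > t_crit, adjacency, min_neighbours)
        for _, stat in _clusters_from_mask(mask, tmap, adjacency):
            best = max(best, abs(stat))
    return best


def cluster_permutation(
    diffs: np.ndarray,
    times: np.ndarray,
    neighbourhood: ChannelNeighbourhood,
    cluster_alpha: float = 0.05,
    min_neighbours: int = 2,
    n_perm: int = 2000,
    seed=0,
) -> list:
    """Cluster-based permutation test on participant difference maps.

    Returns all candidate clusters sorted by corrected p value (the first
    is the maximum cluster, i.e. the one with the lowest p). The cluster
    forming threshold is the two-tailed paired-t critical value at
    ``cluster_alpha``; the null is the distribution of the maximal
    |sum-of-t| under participant-level sign flips (identity permutation
    reproduces the observed maximum by construction).
    """
    diffs = np.asarray(diffs, dtype=float)
    n_part, n_ch, n_t = diffs.shape
    if n_part < 2:
        raise ErpError("need at least 2 participants")
    adjacency = neighbourhood.adjacency
    if adjacency.shape[0] != n_ch:
        raise ErpError("neighbourhood does not cover all channels")
    t_crit = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, n_part - 1))

    t_obs = _tmap(diffs)
    observed = []
    for sign in (1, -1):
        mask = _min_neighbour_filter(sign * t_obs > t_crit, adjacency, min_neighbours)
        for member_mask, stat in _clusters_from_mask(mask, t_obs, adjacency):
            observed.append((member_mask, stat, sign))
    if not observed:
        return []

    # permutation null of the maximal cluster statistic
    rng = np.random.default_rng(_entropy(seed))
    flat = diffs.reshape(n_part, -1)
    sq_sum = np.sum(flat**2, axis=0)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n_part))
    max_stats = np.empty(n_perm)
    for b in range(n_perm):
        mean = (signs[b] @ flat) / n_part
        var = (sq_sum - n_part * mean**2) / (n_part - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_b = np.where(var > 0, mean / np.sqrt(var / n_part), 0.0)
        max_stats[b] = _max_cluster_stat(
            t_b.reshape(n_ch, n_t), t_crit, adjacency, min_neighbours
        )

    results = []
    for member_mask, stat, sign in observed:
        p = (1.0 + np.sum(max_stats >= abs(stat))) / (1.0 + n_perm)
        time_any = member_mask.any(axis=0)
        extent = (float(times[time_any][0]), float(times[time_any][-1]))
        col_sums = np.where(member_mask, t_obs, 0.0).sum(axis=0)
        peak = float(times[np.argmax(np.abs(col_sums))])
        results.append(
            ClusterResult(
                mask=member_mask,
                statistic=stat,
                sign=sign,
                p_value=float(p),
                times=times,
                channel_labels=neighbourhood.channel_labels,
                extent_ms=extent,
                peak_time_ms=peak,
            )
        )
    results.sort(key=lambda r: (r.p_value, -abs(r.statistic)))
    return results


def windowed_retrieval_scan(
    epochs: EpochSet,
    contrast: str,
    neighbourhood: ChannelNeighbourhood,
    full_window: tuple = (-3000.0, 100.0),
    sub_epoch_ms: float = 300.0,
    cluster_alpha: float = 0.05,
    min_neighbours: int = 2,
    n_perm: int = 2000,
    seed=0,
) -> list:
    """Cluster permutation per 300 ms sub-epoch of the retrieval window.

    The last sub-epoch may be shorter than ``sub_epoch_ms``. Results from
    all sub-epochs are concatenated, each carrying its sub-window as
    provenance; correction is within sub-epoch.
    """
    start, end = full_window
    edges = [start]
    while edges[-1] + sub_epoch_ms < end:
        edges.append(edges[-1] + sub_epoch_ms)
    edges.append(end)
    diffs, times, _ = participant_difference_maps(epochs, contrast, full_window)
    results = []
    root = np.random.SeedSequence([_entropy(seed), 11])
    for (lo, hi), stream in zip(zip(edges[:-1], edges[1:]), root.spawn(len(edges) - 1)):
        sel = (times >= lo) & (times < hi) if hi < end else (times >= lo) & (times <= hi)
        if not sel.any():
            continue
        for res in cluster_permutation(
            diffs[:, :, sel],
            times[sel],
            neighbourhood,
            cluster_alpha=cluster_alpha,
            min_neighbours=min_neighbours,
            n_perm=n_perm,
            seed=stream,
        ):
            res.sub_epoch = (float(lo), float(hi))
            results.append(res)
    return results


def participant_peak_times(
    diffs: np.ndarray, times: np.ndarray, cluster_channels: np.ndarray, window: tuple
) -> np.ndarray:
    """Per-participant latency of the maximal |ERP difference|.

    The difference is averaged over the cluster's channels but the maximum
    is searched over the *entire* given window, not only the cluster's
    extent. Ties break toward the earliest time.
    """
    cluster_channels = np.asarray(cluster_channels)
    if cluster_channels.size == 0:
        raise ErpError("empty cluster channel set")
    sel = (times >= window[0]) & (times <= window[1])
    course = diffs[:, cluster_channels, :][:, :, sel].mean(axis=1)
    return times[sel][np.argmax(np.abs(course), axis=1)]


def _entropy(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return int(np.random.default_rng(seed).integers(0, 2**31))
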