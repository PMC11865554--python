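"""Model-informed analysis of step-locked physiological data.

The Receiver watches the message replay one step at a time; epochs locked to
each step are regressed on the model-derived surprise of that step.  The
pipeline is: baseline correction, per-subject mass-univariate regression
(one slope per channel and time point), and a group-level one-sample test
with cluster-based permutation correction over the channel x time map
(sign-flipping whole subjects, cluster statistic = summed t).  For pupil
data a two-stage summary-statistics estimator stands in for a full mixed
model: per-subject OLS slopes of PDR on surprise, then a group-level
one-sample t test — asymptotically the same fixed effect for balanced data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "EpochSet", "ClusterResult", "Cluster", "PdrSlopeResult",
    "chain_channel_graph", "grid_channel_graph",
    "baseline_correct", "epoch_regression", "cluster_permutation_test",
    "pdr_slope_test", "regression_by_message_type",
]


def chain_channel_graph(n_channels: int) -> list[tuple[int, int]]:
    """Channels in a line, each adjacent to its neighbors."""
    return [(i, i + 1) for i in range(n_channels - 1)]


def grid_channel_graph(n_rows: int, n_cols: int) -> list[tuple[int, int]]:
    """Channels on a rows x cols montage with rook adjacency."""
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if c + 1 < n_cols:
                edges.append((i, i + 1))
            if r + 1 < n_rows:
                edges.append((i, i + n_cols))
    return edges


@dataclass
class EpochSet:
    """Step-locked epochs for a cohort.

    ``data``: per-subject arrays of shape (n_epochs, n_channels,
    n_timepoints); ``step_surprise``: per-subject vectors, one value per
    epoch; ``times_ms``: the shared time grid; ``channel_graph``: undirected
    neighbor edges used for spatial clustering.
    """

    data: list[np.ndarray]
    step_surprise: list[np.ndarray]
    times_ms: np.ndarray
    channel_graph: list[tuple[int, int]] = field(default_factory=list)
    baseline_window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if len(self.data) != len(self.step_surprise):
            raise ValueError("one surprise vector per subject is required")
        for ep, h in zip(self.data, self.step_surprise):
            if ep.shape[0] != len(h):
                raise ValueError("one surprise value per epoch is required")
            if ep.shape[2] != len(self.times_ms):
                raise ValueError("epoch length must match the time grid")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_channels(self) -> int:
        return self.data[0].shape[1]


def baseline_correct(epochs: EpochSet, window: tuple[float, float],
                     mode: str = "subtract_mean") -> EpochSet:
    """Subtract the per-epoch, per-channel mean of ``window`` (ms) from every sample."""
    if mode != "subtract_mean":
        raise ValueError("only 'subtract_mean' is implemented")
    lo, hi = window
    mask = (epochs.times_ms >= lo) & (epochs.times_ms < hi)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    data = [ep - ep[:, :, mask].mean(axis=2, keepdims=True) for ep in epochs.data]
    return replace(epochs, data=data, baseline_window=(lo, hi))


def epoch_regression(epochs: EpochSet) -> np.ndarray:
    """Least-squares slope of signal on surprise, per subject/channel/timepoint.

    Fits signal ~ intercept + beta * surprise across a subject's epochs;
    returns betas with shape (n_subjects, n_channels, n_timepoints).
    Subjects with zero surprise variance are rejected.
    """
    betas = []
    for ep, h in zip(epochs.data, epochs.step_surprise):
        if ep.shape[0] < 3:
            raise ValueError("need at least 3 epochs per subject")
        hc = h - h.mean()
        denom = float(hc @ hc)
        if denom <= 0:
            raise ValueError("surprise has zero variance for a subject; "
                             "exclude that subject before regression")
        betas.append(np.tensordot(hc, ep, axes=(0, 0)) / denom)
    return np.stack(betas)


@dataclass
class Cluster:
    """A connected supra-threshold set of (channel, timepoint) cells."""

    points: list[tuple[int, int]]
    mass: float          # summed t values (signed)
    p_value: float


@dataclass
class ClusterResult:
    t_map: np.ndarray
    threshold: float
    clusters: list[Cluster]
    n_permutations: int
    null_max_mass: np.ndarray

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]


def _t_map(betas: np.ndarray) -> np.ndarray:
    n = betas.shape[0]
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def _adjacency(n_channels: int, n_times: int,
               channel_graph: Sequence[tuple[int, int]]) -> sparse.csr_matrix:
    """Sparse adjacency over flattened (channel, time) cells."""
    rows, cols = [], []

    def add(a, b):
        rows.append(a)
        cols.append(b)
        rows.append(b)
        cols.append(a)

    for ch in range(n_channels):
        for t in range(n_times - 1):
            add(ch * n_times + t, ch * n_times + t + 1)
    for a, b in channel_graph:
        for t in range(n_times):
            add(a * n_times + t, b * n_times + t)
    n = n_channels * n_times
    return sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))


def _max_cluster_mass(t_flat: np.ndarray, mask: np.ndarray,
                      adj: sparse.csr_matrix) -> float:
    """Largest |summed t| over connected components of the masked cells."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return 0.0
    sub = adj[idx][:, idx]
    _, labels = connected_components(sub, directed=False)
    masses = np.bincount(labels, weights=t_flat[idx])
    return float(np.abs(masses).max())


def _clusters_from_mask(t_flat: np.ndarray, mask: np.ndarray,
                        adj: sparse.csr_matrix, n_times: int) -> list[tuple[list, float]]:
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    sub = adj[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    out = []
    for k in range(n_comp):
        cells = idx[labels == k]
        points = [(int(c // n_times), int(c % n_times)) for c in cells]
        out.append((points, float(t_flat[cells].sum())))
    return out


def cluster_permutation_test(betas: np.ndarray,
                             channel_graph: Sequence[tuple[int, int]],
                             cluster_alpha: float = 0.005,
                             n_perm: int = 1000,
                             rng: np.random.Generator | int | None = None,
                             ) -> ClusterResult:
    """Family-wise-error-corrected test of betas against zero.

    Cells with one-sample |t| above the two-sided ``cluster_alpha`` quantile
    are clustered under channel-graph x temporal adjacency; cluster mass is
    the summed t.  The null distribution of the maximum |mass| comes from
    random whole-subject sign flips; corrected p values are the rank of each
    observed |mass| in that distribution.
    """
    betas = np.asarray(betas, float)
    n_sub, n_ch, n_t = betas.shape
    if n_sub < 5:
        raise ValueError("need at least 5 subjects for the permutation test")
    if not hasattr(rng, "choice"):  # anything with .choice can drive the flips
        rng = np.random.default_rng(rng)
    threshold = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, df=n_sub - 1))
    adj = _adjacency(n_ch, n_t, channel_graph)

    t_obs = _t_map(betas).reshape(-1)
    pos = _clusters_from_mask(t_obs, t_obs > threshold, adj, n_t)
    neg = _clusters_from_mask(t_obs, t_obs < -threshold, adj, n_t)
    observed = pos + neg

    # permutation null: sign-flip whole subjects, track the max cluster mass
    flat = betas.reshape(n_sub, -1)
    sq_sum = (flat ** 2).sum(axis=0)
    null = np.empty(n_perm)
    for i in range(n_perm):
        signs = rng.choice((-1.0, 1.0), size=n_sub)
        mean = signs @ flat / n_sub
        var = (sq_sum - n_sub * mean ** 2) / (n_sub - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = np.where(var > 0, mean / np.sqrt(var / n_sub), 0.0)
        null[i] = max(_max_cluster_mass(t_p, t_p > threshold, adj),
                      _max_cluster_mass(t_p, t_p < -threshold, adj))

    clusters = []
    for points, mass in observed:
        p = (1.0 + np.sum(null >= abs(mass))) / (1.0 + n_perm)
        clusters.append(Cluster(points=points, mass=mass, p_value=float(p)))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(t_map=t_obs.reshape(n_ch, n_t), threshold=threshold,
                         clusters=clusters, n_permutations=n_perm,
                         null_max_mass=null)


@dataclass
class PdrSlopeResult:
    slope: float
    ci95: tuple[float, float]
    t_statistic: float
    p_value: float
    df: int
    subject_slopes: np.ndarray


def pdr_slope_test(pdr: Sequence[np.ndarray],
                   step_surprise: Sequence[np.ndarray],
                   min_steps: int = 10) -> PdrSlopeResult:
    """Two-stage test of the surprise -> pupil coupling.

    Stage 1 fits an OLS slope of PDR on surprise per subject; stage 2 runs a
    one-sample t test of the slopes against zero and reports the group mean
    slope with its 95% CI.  Subjects with too few steps or degenerate
    surprise are dropped with a warning.
    """
    import warnings
    slopes = []
    for y, h in zip(pdr, step_surprise):
        y, h = np.asarray(y, float), np.asarray(h, float)
        if len(y) < min_steps or np.var(h) == 0:
            warnings.warn("dropping subject with too few steps or constant surprise",
                          stacklevel=2)
            continue
        hc = h - h.mean()
        slopes.append(float(hc @ (y - y.mean()) / (hc @ hc)))
    slopes = np.array(slopes)
    if len(slopes) < 3:
        raise ValueError("need at least 3 usable subjects")
    n = len(slopes)
    mean = slopes.mean()
    se = slopes.std(ddof=1) / np.sqrt(n)
    t_stat = mean / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    half = stats.t.ppf(0.975, df) * se
    return PdrSlopeResult(slope=float(mean), ci95=(float(mean - half), float(mean + half)),
                          t_statistic=float(t_stat), p_value=float(p), df=df,
                          subject_slopes=slopes)


def regression_by_message_type(epochs: EpochSet,
                               message_types: Sequence[Sequence[str]],
                               cluster_mask: np.ndarray,
                               min_epochs: int = 3):
    """Mean beta time-course and mean surprise per message type.

    Re-runs the epoch regression within each message type, averages betas
    over the channels flagged by ``cluster_mask`` (boolean, per channel or
    per channel x time), and pairs each type with its mean model surprise.
    Returns ``{type: (beta_timecourse, mean_surprise)}``; subjects with
    fewer than ``min_epochs`` epochs of a type are excluded for that type.
    """
    cluster_mask = np.asarray(cluster_mask, bool)
    if cluster_mask.ndim == 2:
        ch_mask = cluster_mask.any(axis=1)
    else:
        ch_mask = cluster_mask
    labels = sorted({t for sub in message_types for t in sub})
    out = {}
    for label in labels:
        curves, surprises = [], []
        for ep, h, types in zip(epochs.data, epochs.step_surprise, message_types):
            sel = np.array([t == label for t in types])
            if sel.sum() < min_epochs or np.var(h[sel]) == 0:
                continue
            sub = EpochSet(data=[ep[sel]], step_surprise=[h[sel]],
                           times_ms=epochs.times_ms,
                           channel_graph=epochs.channel_graph)
            beta = epoch_regression(sub)[0]
            curves.append(beta[ch_mask].mean(axis=0))
            surprises.append(float(h[sel].mean()))
        if curves:
            out[label] = (np.stack(curves).mean(axis=0), float(np.mean(surprises)))
    return out
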