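"""Spatiotemporal cluster-based permutation testing for paired ERP contrasts.

The test thresholds a paired-t map over (channel, time) at the two-tailed
alpha = 0.05 t-quantile, groups suprathreshold samples of each sign into
clusters connected over adjacent channels and consecutive time samples, and
sums the member t values into the cluster-level statistic ("clusterstat").
The reference distribution is the per-permutation maximum of |clusterstat|
under independent per-participant condition-label swaps (sign flips of the
difference waves), so both signs are tested jointly. Monte-Carlo p-values
carry the +1 correction; designs with 2^N <= n_permutations switch to exact
exhaustive enumeration. A temporal-only mode (single virtual channel) serves
channel-cluster averages and region time series.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .erp import cohens_d_ci


@dataclass
class SensorLayout:
    """Channel positions and a symmetric, irreflexive adjacency."""

    channel_names: list[str]
    positions: np.ndarray
    adjacency: sparse.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape[0] != len(self.channel_names):
            raise ValueError("positions/channel_names length mismatch")
        if self.adjacency is not None:
            self._check_adjacency()

    def _check_adjacency(self) -> None:
        a = self.adjacency
        if (a != a.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency must be irreflexive")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "name": self.channel_names,
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
            "z": self.positions[:, 2],
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SensorLayout":
        df = pd.read_csv(path, sep="\t")
        return cls(
            channel_names=df["name"].astype(str).tolist(),
            positions=df[["x", "y", "z"]].to_numpy(),
        )


def build_adjacency(
    layout: SensorLayout,
    method: Literal["distance", "knn"] = "distance",
    param: float | None = None,
) -> SensorLayout:
    """Attach a channel adjacency to ``layout``.

    distance method: link channels closer than the radius ``param``
    (default 1.3 x the median nearest-neighbor distance). knn: link each
    channel to its ``param`` nearest neighbors, symmetrized by union.
    Channels left without neighbors trigger a warning, not an error.
    """
    pos = layout.positions
    n = pos.shape[0]
    if n < 2:
        raise ValueError("need >= 2 channels")
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if method == "distance":
        radius = param if param is not None else 1.3 * float(
            np.median(d.min(axis=1))
        )
        adj = d <= radius
    elif method == "knn":
        k = int(param) if param is not None else 1
        adj = np.zeros((n, n), dtype=bool)
        order = np.argsort(d, axis=1)[:, :k]
        for i in range(n):
            adj[i, order[i]] = True
        adj |= adj.T
    else:
        raise ValueError(f"unknown method: {method}")
    np.fill_diagonal(adj, False)
    isolated = np.flatnonzero(~adj.any(axis=1))
    if isolated.size:
        warnings.warn(
            f"channels without neighbors: "
            f"{[layout.channel_names[i] for i in isolated]}"
        )
    return SensorLayout(
        channel_names=list(layout.channel_names),
        positions=pos.copy(),
        adjacency=sparse.csr_matrix(adj),
    )


def paired_t_map(diff: np.ndarray) -> np.ndarray:
    """One-sample t over participants of difference maps, df = N - 1.

    ``diff`` is (participants, channels, time); zero-variance cells get
    signed infinity with a warning.
    """
    diff = np.asarray(diff, dtype=float)
    n = diff.shape[0]
    if n < 2:
        raise ValueError("need >= 2 participants")
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn("zero-variance samples; t set to signed infinity")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(zero, np.sign(mean) * np.inf, t)
    t = np.where(zero & (mean == 0), 0.0, t)
    return t


def paired_t_from_evokeds(cond_a: np.ndarray, cond_b: np.ndarray) -> np.ndarray:
    """t map for per-participant Evoked stacks (participants, ch, time)."""
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conditions must share participants and shape")
    return paired_t_map(a - b)


@dataclass
class Cluster:
    """One suprathreshold cluster with its summary measures."""

    mask: np.ndarray  # boolean (channels, time)
    stat: float
    sign: int
    p: float | None = None
    d: float | None = None
    d_ci: tuple[float, float] | None = None
    onset: float | None = None
    offset: float | None = None
    peak_time: float | None = None
    peak_channel: str | None = None


@dataclass
class ClusterResult:
    """Permutation-test outcome over all clusters of both signs."""

    clusters: list[Cluster]
    n_permutations: int
    alpha: float
    max_stat_distribution: np.ndarray
    exhaustive: bool = False

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p is not None and c.p <= self.alpha]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            rows.append({
                "sign": c.sign, "clusterstat": c.stat, "p": c.p,
                "d": c.d,
                "d_ci_lo": None if c.d_ci is None else c.d_ci[0],
                "d_ci_hi": None if c.d_ci is None else c.d_ci[1],
                "onset_s": c.onset, "offset_s": c.offset,
                "peak_s": c.peak_time, "peak_channel": c.peak_channel,
                "n_channels": int(c.mask.any(axis=1).sum()),
                "n_samples": int(c.mask.sum()),
            })
        return pd.DataFrame(rows)


def _neighbor_lists(adjacency: sparse.spmatrix | None, n_ch: int) -> list[np.ndarray]:
    if adjacency is None:
        return [np.array([], dtype=int)] * n_ch
    csr = sparse.csr_matrix(adjacency)
    return [csr.indices[csr.indptr[i]:csr.indptr[i + 1]] for i in range(n_ch)]


def form_clusters(
    t_map: np.ndarray,
    adjacency: sparse.spmatrix | None,
    threshold_t: float,
) -> list[Cluster]:
    """Group suprathreshold samples by spatiotemporal connectivity.

    Positive (t > +threshold) and negative (t < -threshold) excursions are
    clustered separately; connectivity links the same channel at consecutive
    time samples and adjacent channels at the same time sample. The cluster
    statistic is the sum of member t values.
    """
    if threshold_t <= 0:
        raise ValueError("threshold_t must be positive")
    t_map = np.atleast_2d(np.asarray(t_map, dtype=float))
    n_ch, n_time = t_map.shape
    clusters: list[Cluster] = []
    neighbors = _neighbor_lists(adjacency, n_ch)
    for sign in (1, -1):
        supra = (sign * t_map) > threshold_t
        if not supra.any():
            continue
        # Union-find style flood fill via sparse connected components.
        idx = np.flatnonzero(supra.ravel())
        lookup = -np.ones(n_ch * n_time, dtype=int)
        lookup[idx] = np.arange(idx.size)
        rows, cols = [], []
        ch_i, ti = np.unravel_index(idx, (n_ch, n_time))
        # temporal edges
        right = idx + 1
        ok = (ti < n_time - 1) & (lookup[np.minimum(right, n_ch * n_time - 1)] >= 0)
        rows.extend(lookup[idx[ok]])
        cols.extend(lookup[right[ok]])
        # spatial edges
        for j, (c, t_i) in enumerate(zip(ch_i, ti)):
            for nb in neighbors[c]:
                flat = nb * n_time + t_i
                k = lookup[flat]
                if k >= 0:
                    rows.append(j)
                    cols.append(k)
        graph = sparse.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(idx.size, idx.size)
        )
        n_comp, comp = sparse.csgraph.connected_components(graph, directed=False)
        for label in range(n_comp):
            members = idx[comp == label]
            mask = np.zeros((n_ch, n_time), dtype=bool)
            mask.ravel()[members] = True
            clusters.append(Cluster(
                mask=mask,
                stat=float(t_map.ravel()[members].sum()),
                sign=sign,
            ))
    clusters.sort(key=lambda c: -abs(c.stat))
    return clusters


def _max_cluster_stat(t_map, adjacency, threshold_t) -> float:
    cl = form_clusters(t_map, adjacency, threshold_t)
    return max((abs(c.stat) for c in cl), default=0.0)


def permutation_test(
    diff: np.ndarray,
    adjacency: sparse.spmatrix | None = None,
    n_permutations: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    times: np.ndarray | None = None,
    channel_names: Sequence[str] | None = None,
    d_ci_boot: int = 2000,
    force_monte_carlo: bool = False,
) -> ClusterResult:
    """Max-statistic cluster permutation test on paired difference maps.

    ``diff`` holds the per-participant condition differences, shape
    (participants, channels, time) — or (participants, time) for the
    temporal-only mode. The sample threshold is the two-tailed alpha
    t-quantile at df = N - 1; each permutation flips a random subset of
    participants' signs and records the maximum |clusterstat|; observed
    clusters get p = (1 + #{maxima >= |stat|}) / (1 + n_permutations).
    When 2^N <= n_permutations the full sign-flip set is enumerated instead
    (exact test, p over 2^N flips). Significant clusters carry a Cohen's d
    over participant means within the cluster mask, with a seeded BCa
    bootstrap CI.
    """
    diff = np.asarray(diff, dtype=float)
    if diff.ndim == 2:
        diff = diff[:, None, :]
    n = diff.shape[0]
    if n < 2:
        raise ValueError("paired design needs >= 2 participants")
    threshold_t = float(stats.t.ppf(1 - alpha / 2, df=n - 1))
    observed_t = paired_t_map(diff)
    clusters = form_clusters(observed_t, adjacency, threshold_t)

    exhaustive = (2 ** n <= n_permutations) and not force_monte_carlo
    if exhaustive:
        signs_iter = itertools.product((1.0, -1.0), repeat=n)
        maxima = np.array([
            _max_cluster_stat(
                paired_t_map(diff * np.array(s)[:, None, None]),
                adjacency, threshold_t,
            )
            for s in signs_iter
        ])
        denom = maxima.size  # exact: includes the identity flip
        for c in clusters:
            c.p = float(np.sum(maxima >= abs(c.stat) - 1e-12) / denom)
    else:
        rng = np.random.default_rng(seed)
        maxima = np.empty(n_permutations)
        for i in range(n_permutations):
            s = rng.choice((1.0, -1.0), size=n)[:, None, None]
            maxima[i] = _max_cluster_stat(
                paired_t_map(diff * s), adjacency, threshold_t
            )
        for c in clusters:
            c.p = float(
                (1 + np.sum(maxima >= abs(c.stat) - 1e-12))
                / (1 + n_permutations)
            )

    for c in clusters:
        if c.p is not None and c.p <= alpha:
            per_part = np.array([
                diff[i][c.mask].mean() for i in range(n)
            ])
            sd = per_part.std(ddof=1)
            c.d = float(per_part.mean() / sd) if sd > 0 else np.nan
            if sd > 0:
                c.d_ci = cohens_d_ci(per_part, n_boot=d_ci_boot, seed=seed)
        if times is not None:
            tsel = np.flatnonzero(c.mask.any(axis=0))
            c.onset = float(times[tsel[0]])
            c.offset = float(times[tsel[-1]])
            peak_flat = np.argmax(np.abs(np.where(c.mask, observed_t, 0.0)))
            pc, pt = np.unravel_index(peak_flat, c.mask.shape)
            c.peak_time = float(times[pt])
            if channel_names is not None:
                c.peak_channel = str(channel_names[pc])

    return ClusterResult(
        clusters=clusters,
        n_permutations=n_permutations,
        alpha=alpha,
        max_stat_distribution=maxima,
        exhaustive=exhaustive,
    )
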