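"""Cluster-corrected permutation inference for participant x time(-frequency) data.

Two tests are provided:

* ``sign_permutation_cluster_test`` — one-sample test against a null value
  (e.g. decoding accuracy vs. 50% chance).  The null distribution is built
  by flipping the sign of each participant's whole deviation series with 50%
  probability and recording the maximum cluster statistic per permutation.
* ``paired_cluster_permutation_test`` — paired comparison of two conditions
  (e.g. contralateral vs. ipsilateral power).  Exchanging a participant's
  condition labels is equivalent to flipping the sign of their difference
  series, so the same engine runs on A - B; the cluster statistic defaults
  to the cluster size (number of supra-threshold points) and a cluster is
  significant when its size exceeds the 95th percentile of the permutation
  maximum-size distribution.

Clusters are contiguous runs of timepoints (for 2-D time-frequency input:
4-connected voxels) whose pointwise t statistic exceeds the t-distribution
critical value at the cluster-forming alpha.  Positive and negative
deviations form separate clusters; a one-sided test considers one sign only.
P-values use the add-one permutation estimator (1 + b) / (1 + m), which can
never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

_T_CAP = 1e12  # cap infinite t (zero variance, nonzero mean) to keep sums finite


def _count_ge(perm_max: np.ndarray, stat: float) -> int:
    """Count permutation maxima >= stat, tolerating float round-off ties.

    The permutation engine computes t from sign-flipped sums in a different
    arithmetic order than the observed path, so replicates that reproduce the
    observed statistic exactly can land a few ulps below it; those ties must
    count (the add-one estimator assumes the observed arrangement is included).
    """
    tol = 1e-8 * (1.0 + abs(stat))
    return int(np.sum(perm_max >= stat - tol))


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    cluster_stat: float
    p_value: float
    significant: bool
    n_points: int
    freq_range: tuple[float, float] | None = None


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    alpha: float
    n_permutations: int
    sidedness: str
    cluster_stat_kind: str
    analysis_window: tuple[float, float]
    null_max_percentile_95: float
    times: np.ndarray = field(repr=False, default=None)

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.clusters)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "sidedness": self.sidedness,
            "cluster_stat_kind": self.cluster_stat_kind,
            "analysis_window": list(self.analysis_window),
            "null_max_percentile_95": self.null_max_percentile_95,
            "clusters": [
                {
                    "start_ms": c.start_ms,
                    "end_ms": c.end_ms,
                    "cluster_stat": c.cluster_stat,
                    "p_value": c.p_value,
                    "significant": c.significant,
                    "n_points": c.n_points,
                    "freq_range": None if c.freq_range is None else list(c.freq_range),
                }
                for c in self.clusters
            ],
        }


def _tails(sidedness: str) -> list[int]:
    if sidedness == "greater":
        return [1]
    if sidedness == "less":
        return [-1]
    if sidedness == "two-sided":
        return [1, -1]
    raise ValueError(f"sidedness must be 'greater', 'less' or 'two-sided', got {sidedness!r}")


def _one_sample_t(x: np.ndarray) -> np.ndarray:
    """One-sample t across axis 0, with 0/0 -> 0 and capped infinities."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(np.isnan(t), 0.0, t)
    return np.clip(t, -_T_CAP, _T_CAP)


def _perm_t(x2d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t maps for sign-flipped replicates: signs (R x n) applied to x2d (n x V)."""
    n = x2d.shape[0]
    mean = signs @ x2d / n  # R x V
    ss = np.sum(x2d**2, axis=0)[None, :]  # invariant under sign flips
    var = (ss - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t = np.where(np.isnan(t), 0.0, t)
    return np.clip(t, -_T_CAP, _T_CAP)


def _max_cluster_stat_rows(
    tmat: np.ndarray, thresh: float, tails: list[int], kind: str
) -> np.ndarray:
    """Per row of ``tmat`` (R x T), the largest cluster statistic (0 if none)."""
    R, T = tmat.shape
    best = np.zeros(R)
    for sign in tails:
        st = sign * tmat
        padded = np.zeros((R, T + 2))
        padded[:, 1:-1] = st
        mask = (padded > thresh).reshape(-1)
        diff = np.diff(mask.astype(np.int8))
        starts = np.flatnonzero(diff == 1) + 1
        ends = np.flatnonzero(diff == -1) + 1  # exclusive
        if starts.size == 0:
            continue
        if kind == "size":
            vals = (ends - starts).astype(float)
        else:
            cs = np.concatenate([[0.0], np.cumsum(padded.reshape(-1))])
            vals = cs[ends] - cs[starts]
        rows = starts // (T + 2)
        np.maximum.at(best, rows, vals)
    return best


def _observed_clusters_1d(
    t: np.ndarray, thresh: float, tails: list[int], kind: str
) -> list[tuple[int, int, float]]:
    """(start_idx, end_idx_inclusive, stat) for each supra-threshold run."""
    out = []
    for sign in tails:
        mask = sign * t > thresh
        if not mask.any():
            continue
        padded = np.concatenate([[False], mask, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive
        for s, e in zip(starts, ends):
            stat = float(e - s) if kind == "size" else float(np.sum(sign * t[s:e]))
            out.append((int(s), int(e - 1), stat))
    out.sort(key=lambda c: c[0])
    return out


def _window_mask(times: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones(times.size, dtype=bool)
    lo, hi = window
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError(f"analysis window {window} contains no timepoints")
    return mask


def sign_permutation_cluster_test(
    values: np.ndarray,
    times: np.ndarray,
    null_value: float = 0.5,
    n_perm: int = 100_000,
    alpha: float = 0.05,
    sidedness: str = "greater",
    cluster_stat_kind: str = "mass",
    window: tuple[float, float] | None = None,
    rng: np.random.Generator | int | None = None,
) -> ClusterResult:
    """One-sample cluster permutation test of ``values`` against ``null_value``.

    ``values`` is participants x time.  Each permutation flips every
    participant's entire deviation series with probability 0.5 and records
    the maximum cluster statistic; a cluster's p-value is the add-one
    fraction of permutation maxima at least as large as its statistic.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be participants x time")
    n = values.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 participants, got {n}")
    if cluster_stat_kind not in ("mass", "size"):
        raise ValueError(f"cluster_stat_kind must be 'mass' or 'size', got {cluster_stat_kind!r}")
    times = np.asarray(times, dtype=float)
    if times.size != values.shape[1]:
        raise ValueError("times length does not match values")
    tails = _tails(sidedness)
    rng = np.random.default_rng(rng)
    mask = _window_mask(times, window)
    x = values[:, mask] - null_value
    wtimes = times[mask]
    df = n - 1
    point_alpha = alpha if len(tails) == 1 else alpha / 2
    thresh = float(stats.t.ppf(1 - point_alpha, df))

    t_obs = _one_sample_t(x)
    observed = _observed_clusters_1d(t_obs, thresh, tails, cluster_stat_kind)

    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm_max = _max_cluster_stat_rows(_perm_t(x, signs), thresh, tails, cluster_stat_kind)
    p95 = float(np.percentile(perm_max, 95)) if n_perm > 0 else np.inf

    clusters = []
    for s, e, stat in observed:
        p = (1.0 + _count_ge(perm_max, stat)) / (1.0 + n_perm)
        clusters.append(
            Cluster(
                start_ms=float(wtimes[s]),
                end_ms=float(wtimes[e]),
                cluster_stat=stat,
                p_value=float(p),
                significant=bool(p <= alpha),
                n_points=e - s + 1,
            )
        )
    lo, hi = (float(wtimes[0]), float(wtimes[-1]))
    return ClusterResult(
        clusters=clusters,
        alpha=alpha,
        n_permutations=n_perm,
        sidedness=sidedness,
        cluster_stat_kind=cluster_stat_kind,
        analysis_window=(lo, hi),
        null_max_percentile_95=p95,
        times=wtimes,
    )


def paired_cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    times: np.ndarray,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    sidedness: str = "two-sided",
    cluster_stat_kind: str = "size",
    window: tuple[float, float] | None = None,
    frequencies: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> ClusterResult:
    """Paired label-exchange cluster test between two conditions.

    ``cond_a`` and ``cond_b`` are participants x time or participants x
    frequency x time.  Per permutation each participant's (A, B) pair is
    swapped with probability 0.5 (equivalently: the sign of A - B flipped)
    and the size of the largest supra-threshold cluster is recorded.  A
    cluster is significant when its statistic strictly exceeds the 95th
    percentile of that maximum-cluster distribution (for ``alpha=0.05``;
    generally the (1 - alpha) quantile).
    """
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    if cond_a.shape != cond_b.shape:
        raise ValueError(
            f"condition arrays must have the same shape, got {cond_a.shape} vs {cond_b.shape}"
        )
    if cond_a.ndim not in (2, 3):
        raise ValueError("conditions must be participants x time or participants x freq x time")
    n = cond_a.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 participants, got {n}")
    if cluster_stat_kind not in ("mass", "size"):
        raise ValueError(f"cluster_stat_kind must be 'mass' or 'size', got {cluster_stat_kind!r}")
    times = np.asarray(times, dtype=float)
    if times.size != cond_a.shape[-1]:
        raise ValueError("times length does not match condition arrays")
    tails = _tails(sidedness)
    rng = np.random.default_rng(rng)
    mask = _window_mask(times, window)
    d = (cond_a - cond_b)[..., mask]
    wtimes = times[mask]
    df = n - 1
    point_alpha = alpha if len(tails) == 1 else alpha / 2
    thresh = float(stats.t.ppf(1 - point_alpha, df))
    t_obs = _one_sample_t(d)

    if d.ndim == 2:
        observed = [
            (s, e, stat, None, e - s + 1)
            for s, e, stat in _observed_clusters_1d(t_obs, thresh, tails, cluster_stat_kind)
        ]
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        perm_max = _max_cluster_stat_rows(_perm_t(d, signs), thresh, tails, cluster_stat_kind)
    else:
        observed = _observed_clusters_2d(t_obs, thresh, tails, cluster_stat_kind, frequencies)
        perm_max = _perm_max_2d(d, thresh, tails, cluster_stat_kind, n_perm, rng)

    cutoff = float(np.quantile(perm_max, 1 - alpha)) if n_perm > 0 else np.inf
    clusters = []
    for s, e, stat, frange, npts in observed:
        p = (1.0 + _count_ge(perm_max, stat)) / (1.0 + n_perm)
        tol = 1e-8 * (1.0 + abs(stat))
        clusters.append(
            Cluster(
                start_ms=float(wtimes[s]),
                end_ms=float(wtimes[e]),
                cluster_stat=stat,
                p_value=float(p),
                significant=bool(stat > cutoff + tol),
                n_points=npts,
                freq_range=frange,
            )
        )
    return ClusterResult(
        clusters=clusters,
        alpha=alpha,
        n_permutations=n_perm,
        sidedness=sidedness,
        cluster_stat_kind=cluster_stat_kind,
        analysis_window=(float(wtimes[0]), float(wtimes[-1])),
        null_max_percentile_95=cutoff,
        times=wtimes,
    )


def _observed_clusters_2d(
    t: np.ndarray,
    thresh: float,
    tails: list[int],
    kind: str,
    frequencies: np.ndarray | None,
) -> list[tuple[int, int, float, tuple[float, float] | None, int]]:
    out = []
    structure = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
    for sign in tails:
        mask = sign * t > thresh
        labels, n_lab = ndimage.label(mask, structure=structure)
        for lab in range(1, n_lab + 1):
            where = labels == lab
            fidx, tidx = np.where(where)
            stat = float(where.sum()) if kind == "size" else float(np.sum(sign * t[where]))
            frange = None
            if frequencies is not None:
                frange = (float(frequencies[fidx.min()]), float(frequencies[fidx.max()]))
            out.append((int(tidx.min()), int(tidx.max()), stat, frange, int(where.sum())))
    out.sort(key=lambda c: c[0])
    return out


def _perm_max_2d(
    d: np.ndarray,
    thresh: float,
    tails: list[int],
    kind: str,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 500,
) -> np.ndarray:
    n, nf, nt = d.shape
    d2 = d.reshape(n, nf * nt)
    structure = ndimage.generate_binary_structure(2, 1)
    perm_max = np.zeros(n_perm)
    for lo in range(0, n_perm, chunk):
        hi = min(lo + chunk, n_perm)
        signs = rng.choice([-1.0, 1.0], size=(hi - lo, n))
        tmats = _perm_t(d2, signs).reshape(hi - lo, nf, nt)
        for r in range(hi - lo):
            best = 0.0
            for sign in tails:
                mask = sign * tmats[r] > thresh
                labels, n_lab = ndimage.label(mask, structure=structure)
                if n_lab == 0:
                    continue
                if kind == "size":
                    best = max(best, float(np.bincount(labels.ravel())[1:].max()))
                else:
                    sums = ndimage.sum_labels(sign * tmats[r], labels, range(1, n_lab + 1))
                    best = max(best, float(np.max(sums)))
            perm_max[lo + r] = best
    return perm_max
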