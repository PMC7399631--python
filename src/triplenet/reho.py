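"""Regional homogeneity (ReHo): Kendall's coefficient of concordance over
voxel neighborhoods, mask-mean standardization, and voxelwise group testing
with a permutation cluster-size correction.

ReHo measures the concordance W of a voxel's ranked time series with its 26
nearest neighbors.  Ranks use midranks for ties but the classic formulation's
denominator omits the tie-correction term (a tie-corrected variant is
available).  Group differences are assessed by a voxelwise two-sample t-test;
multiple comparisons are handled by a cluster-size null built from group-label
permutations, with 26-connected clusters to mirror the ReHo neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ReHoMap:
    """3D concordance volume with its brain mask.

    In-mask values lie in (0, 1] before standardization; voxels where W is
    undefined (fewer than 2 in-mask rankers) are NaN and listed in
    ``undefined``.  After standardization the in-mask mean is 1.
    """

    volume: np.ndarray
    mask: np.ndarray
    standardized: bool = False
    undefined: np.ndarray | None = None


@dataclass
class Cluster:
    """A suprathreshold 26-connected voxel cluster from the group test."""

    size: int
    sign: int
    p_value: float
    voxels: np.ndarray  # (size, 3) integer coordinates


def _w_from_ranks(ranks: np.ndarray, tie_corrected: bool = False) -> float:
    """Kendall's W from an m x T midrank array (no tie-correction by default)."""
    m, t = ranks.shape
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    denom = float(m**2 * (t**3 - t))
    if tie_corrected:
        correction = sum(
            float(np.sum(counts**3 - counts))
            for counts in (np.unique(row, return_counts=True)[1] for row in ranks)
        )
        denom -= m * correction
    if denom <= 0:
        return float("nan")
    return 12.0 * s / denom


def kendalls_w(series_set: np.ndarray, tie_tolerant: bool = False, tie_corrected: bool = False) -> float:
    """Kendall's coefficient of concordance of m time series of length T.

    W = 12 * sum_t (R_t - mean R)^2 / (m^2 (T^3 - T)), with R_t the
    cross-series rank sum at timepoint t and midranks for ties.  A constant
    series has undefined rank order and raises unless ``tie_tolerant``.
    """
    series = np.atleast_2d(np.asarray(series_set, dtype=float))
    m, t = series.shape
    if m < 2 or t < 2:
        raise ValueError("need at least 2 series of length at least 2")
    if not tie_tolerant and np.any(series.std(axis=1) == 0):
        raise ValueError("constant series has undefined ranks")
    ranks = stats.rankdata(series, axis=1)
    return _w_from_ranks(ranks, tie_corrected=tie_corrected)


def reho_map(
    volume4d: np.ndarray,
    mask: np.ndarray,
    full_neighborhood_only: bool = False,
) -> ReHoMap:
    """Voxelwise Kendall's W over each voxel and its in-mask 26-neighborhood.

    Edge voxels use whatever in-mask neighbors are available (m <= 27); a
    voxel with fewer than 2 in-mask rankers (or, in full-neighborhood mode,
    fewer than 27) is flagged undefined.  The computation is vectorized:
    per-voxel time ranks are summed over the neighborhood by 3x3x3 box
    correlation, which is exactly the per-voxel rank-sum formula.
    """
    volume4d = np.asarray(volume4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume4d.shape[:-1]:
        raise ValueError("mask and volume grids differ")
    if not mask.any():
        raise ValueError("empty mask")
    t = volume4d.shape[-1]
    if t < 2:
        raise ValueError("need at least 2 timepoints")

    ranks = stats.rankdata(volume4d, axis=-1)
    ranks[~mask] = 0.0
    kernel = np.ones((3, 3, 3, 1))
    # rank sum over the 27-voxel box at every timepoint, zeros outside grid
    rank_sums = ndimage.correlate(ranks, kernel, mode="constant", cval=0.0)
    m_count = ndimage.correlate(
        mask.astype(float), np.ones((3, 3, 3)), mode="constant", cval=0.0
    )
    m_count = np.rint(m_count)

    mean_sum = rank_sums.mean(axis=-1, keepdims=True)
    s = np.sum((rank_sums - mean_sum) ** 2, axis=-1)
    denom = m_count**2 * (t**3 - t)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, 12.0 * s / denom, np.nan)

    min_m = 27 if full_neighborhood_only else 2
    undefined = mask & (m_count < min_m)
    w[undefined] = np.nan
    w[~mask] = 0.0
    return ReHoMap(volume=w, mask=mask, standardized=False, undefined=undefined)


def standardize_reho(reho: ReHoMap) -> ReHoMap:
    """Divide every in-mask value by the in-mask mean (subject-level scaling)."""
    values = reho.volume[reho.mask]
    mean = float(np.nanmean(values))
    if not mean > 0:
        raise ValueError("in-mask mean must be positive")
    out = reho.volume.copy()
    out[reho.mask] = reho.volume[reho.mask] / mean
    return ReHoMap(
        volume=out, mask=reho.mask, standardized=True, undefined=reho.undefined
    )


def _voxelwise_t(data: np.ndarray, is_patient: np.ndarray) -> np.ndarray:
    """Pooled two-sample t statistic per voxel (patient minus control)."""
    a, b = data[is_patient], data[~is_patient]
    n1, n2 = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t


def _max_cluster_size(supra: np.ndarray) -> int:
    labeled, n = ndimage.label(supra, structure=_CONNECTIVITY_26)
    if n == 0:
        return 0
    return int(np.bincount(labeled.ravel())[1:].max())


def reho_group_test(
    maps: list[ReHoMap],
    labels: list[str],
    voxel_alpha: float = 0.01,
    cluster_alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int | None = None,
    patient_label: str = "patient",
) -> tuple[np.ndarray, list[Cluster]]:
    """Voxelwise t-test with permutation cluster-size correction.

    Suprathreshold voxels (two-sided p < voxel_alpha) are grouped into
    26-connected clusters separately by sign; the null distribution of the
    maximum cluster size (either sign) comes from ``n_permutations`` random
    group-label permutations.  A cluster is significant when its size exceeds
    the (1 - cluster_alpha) null quantile.  Zero-variance voxels are excluded.
    """
    import warnings

    if n_permutations < 100:
        warnings.warn(
            "fewer than 100 permutations gives a coarse cluster null",
            RuntimeWarning,
            stacklevel=2,
        )
    labels = list(labels)
    is_patient = np.array([lab == patient_label for lab in labels])
    if is_patient.sum() < 2 or (~is_patient).sum() < 2:
        raise ValueError("each group needs at least 2 maps")
    mask = maps[0].mask
    for m in maps:
        if m.mask.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise ValueError("maps are not aligned on a common mask")
    data = np.stack([np.nan_to_num(m.volume) for m in maps])  # n x X x Y x Z
    n1, n2 = int(is_patient.sum()), int((~is_patient).sum())
    df = n1 + n2 - 2
    t_crit = stats.t.ppf(1.0 - voxel_alpha / 2.0, df)

    valid = mask & (data.var(axis=0) > 0)
    t_map = _voxelwise_t(data, is_patient)
    t_map = np.where(valid, t_map, 0.0)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = rng.permutation(is_patient)
        t_perm = np.where(valid, _voxelwise_t(data, perm), 0.0)
        null_max[p] = _max_cluster_size(np.abs(t_perm) > t_crit)
    size_cutoff = float(np.quantile(null_max, 1.0 - cluster_alpha))

    clusters: list[Cluster] = []
    for sign in (+1, -1):
        supra = (sign * t_map) > t_crit
        labeled, n_found = ndimage.label(supra, structure=_CONNECTIVITY_26)
        for cid in range(1, n_found + 1):
            coords = np.argwhere(labeled == cid)
            size = coords.shape[0]
            if size > size_cutoff:
                p_cluster = float((np.sum(null_max >= size) + 1) / (n_permutations + 1))
                clusters.append(
                    Cluster(size=size, sign=sign, p_value=p_cluster, voxels=coords)
                )
    clusters.sort(key=lambda c: -c.size)
    return t_map, clusters
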