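"""Time-course utilities: motion QC, confound regression, band-pass filtering,
dual regression, and spatial template matching of component maps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SubjectQC:
    subject_id: str
    mean_fd: float
    excluded: bool


@dataclass
class SpatialMap:
    """A component spatial map (Z-statistic values) with its brain mask."""

    map_id: str
    volume: np.ndarray
    mask: np.ndarray
    network_label: str | None = None

    def __post_init__(self) -> None:
        if self.volume.shape != self.mask.shape:
            raise ValueError("volume and mask must share shape")

    def in_mask(self) -> np.ndarray:
        return self.volume[self.mask]


@dataclass
class MatchResult:
    pairs: dict[str, list[str]]
    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    merged: dict[str, np.ndarray] = field(default_factory=dict)


def qc_exclude(
    fd_values: list[float],
    subject_ids: list[str] | None = None,
    n_sd: float = 2.0,
) -> list[SubjectQC]:
    """Flag subjects whose mean frame-wise displacement is an outlier.

    A subject is excluded when mean FD exceeds the sample mean by more than
    ``n_sd`` population (n-denominator) standard deviations.  With identical
    FDs the SD is zero and nobody is excluded.
    """
    fd = np.asarray(fd_values, dtype=float)
    if fd.size < 3:
        raise ValueError("need at least 3 subjects for outlier exclusion")
    if np.any(fd < 0):
        raise ValueError("FD values must be nonnegative")
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(fd.size)]
    cutoff = fd.mean() + n_sd * fd.std()  # population SD; zero SD excludes nobody
    return [
        SubjectQC(subject_id=sid, mean_fd=float(v), excluded=bool(v > cutoff))
        for sid, v in zip(subject_ids, fd, strict=True)
    ]


def regress_confounds(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualize time courses against confound regressors (plus intercept).

    ``series`` is signals x timepoints; ``confounds`` is timepoints x
    regressors.  Residuals are orthogonal to every confound column and to the
    intercept (i.e. demeaned).
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    t = series.shape[1]
    if confounds.shape[0] != t:
        raise ValueError("series and confounds must share the number of timepoints")
    design = np.column_stack([np.ones(t), confounds])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns whose removal restores full rank
        aliased = [
            str(c - 1)
            for c in range(1, design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, c, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient confounds (collinear columns: {aliased})")
    beta, *_ = np.linalg.lstsq(design, series.T, rcond=None)
    return series - (design @ beta).T


def bandpass(
    series: np.ndarray, tr: float, low: float = 0.005, high: float = 0.1
) -> np.ndarray:
    """Brick-wall FFT band-pass: keep Fourier bins with frequency in [low, high].

    The zero-frequency (mean) bin is removed whenever ``low`` > 0.  Exactly
    invertible on the retained band and idempotent for identical bands.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    nyquist = 1.0 / (2.0 * tr)
    if not 0 <= low < high:
        raise ValueError("need 0 <= low < high")
    if high > nyquist + 1e-12:
        raise ValueError(f"high cutoff {high} Hz above Nyquist {nyquist:.4g} Hz")
    t = series.shape[1]
    freqs = np.fft.rfftfreq(t, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    spectrum = np.fft.rfft(series, axis=1)
    spectrum[:, ~keep] = 0.0
    return np.fft.irfft(spectrum, n=t, axis=1)


def dual_regression_stage1(
    volume4d: np.ndarray, maps: list[SpatialMap]
) -> np.ndarray:
    """Recover per-map subject time courses by spatial regression.

    Each timepoint's 3D frame is regressed (with intercept) on the stacked
    spatial maps over in-mask voxels; the returned array is
    ``len(maps) x timepoints`` of regression coefficients.
    """
    if not maps:
        raise ValueError("need at least one spatial map")
    mask = maps[0].mask
    for m in maps:
        if m.volume.shape != volume4d.shape[:-1] or m.mask.shape != mask.shape:
            raise ValueError("maps must share grid shape with the 4D volume")
    voxels = volume4d[mask]  # n_vox x T
    design = np.column_stack([np.ones(voxels.shape[0])] + [m.volume[mask] for m in maps])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear spatial maps")
    beta, *_ = np.linalg.lstsq(design, voxels, rcond=None)
    return beta[1:, :]  # drop intercept row


def match_templates(
    sources: list[SpatialMap],
    targets: list[SpatialMap],
    threshold: float = 0.25,
    z_threshold: float = 4.0,
) -> MatchResult:
    """Match component maps to reference templates by in-mask correlation.

    Each source is matched to every target whose Pearson correlation over
    in-mask voxels reaches ``threshold``.  A source matching several targets
    gets a merged mask: the voxelwise maximum of the matched maps, binarized
    at ``z_threshold``.  Zero-variance maps yield no match, with a warning.
    """
    pairs: dict[str, list[str]] = {}
    scores: dict[tuple[str, str], float] = {}
    merged: dict[str, np.ndarray] = {}
    for src in sources:
        matched: list[str] = []
        sv = src.in_mask()
        for tgt in targets:
            tv = tgt.volume[src.mask]
            if sv.std() == 0 or tv.std() == 0:
                warnings.warn(
                    f"zero-variance map in pair ({src.map_id}, {tgt.map_id}); no match",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            r = float(np.corrcoef(sv, tv)[0, 1])
            scores[(src.map_id, tgt.map_id)] = r
            if r >= threshold:
                matched.append(tgt.map_id)
        pairs[src.map_id] = matched
        if len(matched) > 1:
            stack = np.stack(
                [t.volume for t in targets if t.map_id in matched], axis=0
            )
            merged[src.map_id] = (stack.max(axis=0) >= z_threshold) & src.mask
    return MatchResult(pairs=pairs, scores=scores, merged=merged)
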