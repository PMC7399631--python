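"""Fisher-Z functional connectivity matrices from component time courses.

Each subject contributes a K x K matrix of Fisher Z-transformed Pearson
correlations between component time-course pairs ("functional connectivity
scores").  The diagonal is undefined and stored as zero by convention; it is
excluded from all downstream tests and graph construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_cohort import ComponentTimeSeriesSet

#: correlations with |r| above this bound are clamped before arctanh so the
#: Fisher-Z score stays finite; hitting the bound flags a pathological input.
CLAMP_BOUND = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Per-subject symmetric K x K Fisher-Z connectivity matrix."""

    subject_id: str
    z: np.ndarray
    component_labels: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.z.shape[0]

    def edge_values(self) -> dict[tuple[int, int], float]:
        """Map unordered off-diagonal index pairs to Z scores."""
        k = self.n_components
        return {(i, j): float(self.z[i, j]) for i in range(k) for j in range(i + 1, k)}

    def to_frame(self) -> pd.DataFrame:
        labels = [lab for lab, _net in self.component_labels] or [
            f"c{i}" for i in range(self.n_components)
        ]
        return pd.DataFrame(self.z, index=labels, columns=labels)


def fisher_z(r):
    """Fisher Z-transform arctanh(r) of a correlation coefficient.

    Values with ``|r| >= 1 - 1e-7`` are clamped to that bound (with a warning)
    so that degenerate correlations map to a large finite score.  Values
    outside [-1, 1] beyond floating tolerance raise ``ValueError``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    clipped = np.clip(r, -1.0, 1.0)
    if np.any(np.abs(clipped) >= CLAMP_BOUND):
        warnings.warn(
            "correlation at or beyond the clamp bound; Fisher-Z clamped",
            RuntimeWarning,
            stacklevel=2,
        )
        clipped = np.clip(clipped, -CLAMP_BOUND, CLAMP_BOUND)
    out = np.arctanh(clipped)
    return float(out) if out.ndim == 0 else out


def connectivity_matrix(ts: ComponentTimeSeriesSet) -> ConnectivityMatrix:
    """Pairwise Fisher-Z Pearson correlations of the K component time courses."""
    series = np.asarray(ts.series, dtype=float)
    if series.shape[0] < 2:
        raise ValueError("need at least two components")
    sd = series.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"component {bad} has a constant time course")
    r = np.corrcoef(series)
    z = fisher_z(r - np.eye(series.shape[0]))  # zero the diagonal before transform
    z = np.asarray(z)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # exact symmetry despite floating noise
    labels = list(getattr(ts, "component_labels", []) or [])
    return ConnectivityMatrix(subject_id=ts.subject_id, z=z, component_labels=labels)


def group_mean_matrix(
    matrices: list[ConnectivityMatrix],
    groups: list[str],
    group: str,
) -> np.ndarray:
    """Entrywise mean Fisher-Z matrix over the subjects of one group."""
    sel = [m for m, g in zip(matrices, groups, strict=True) if g == group]
    if not sel:
        raise ValueError(f"no matrices in group {group!r}")
    k = sel[0].n_components
    labels = sel[0].component_labels
    for m in sel[1:]:
        if m.n_components != k or m.component_labels != labels:
            raise ValueError("mixed component labelings across subjects")
    return np.mean([m.z for m in sel], axis=0)


def matrix_to_edge_table(matrix: ConnectivityMatrix) -> pd.DataFrame:
    """Long-format (component_i, component_j, z) edge table."""
    rows = [
        {"component_i": i, "component_j": j, "z": v}
        for (i, j), v in matrix.edge_values().items()
    ]
    return pd.DataFrame(rows)
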