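"""TSV / JSON / NIfTI readers and writers for pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .synthetic_cohort import BehavioralRecord, ComponentTimeSeriesSet


def write_timeseries_tsv(ts: ComponentTimeSeriesSet, path: str | Path) -> Path:
    """One subject's K x T time courses: rows = components, columns = timepoints."""
    path = Path(path)
    labels = [lab for lab, _ in ts.component_labels] or [
        f"c{i}" for i in range(ts.series.shape[0])
    ]
    frame = pd.DataFrame(ts.series, index=labels)
    frame.to_csv(path, sep="\t", header=False, float_format="%.6g")
    return path


def read_timeseries_tsv(
    path: str | Path, subject_id: str, group: str, tr: float
) -> ComponentTimeSeriesSet:
    frame = pd.read_csv(path, sep="\t", header=None, index_col=0)
    labels = [(str(ix), "") for ix in frame.index]
    return ComponentTimeSeriesSet(
        subject_id=subject_id,
        group=group,
        series=frame.to_numpy(dtype=float),
        tr=tr,
        component_labels=labels,
    )


def write_cohort(
    subjects: list[ComponentTimeSeriesSet],
    records: list[BehavioralRecord],
    out_dir: str | Path,
) -> Path:
    """Cohort manifest + per-subject time-course TSVs + behavior table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for ts in subjects:
        fname = f"{ts.subject_id}_timeseries.tsv"
        write_timeseries_tsv(ts, out_dir / fname)
        manifest_rows.append(
            {"subject_id": ts.subject_id, "group": ts.group, "tr": ts.tr, "file": fname}
        )
    pd.DataFrame(manifest_rows).to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
    pd.DataFrame([vars(r) for r in records]).to_csv(
        out_dir / "behavior.tsv", sep="\t", index=False
    )
    return out_dir


def read_cohort(
    cohort_dir: str | Path,
) -> tuple[list[ComponentTimeSeriesSet], list[BehavioralRecord]]:
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "cohort.tsv", sep="\t")
    subjects = [
        read_timeseries_tsv(
            cohort_dir / row["file"], row["subject_id"], row["group"], float(row["tr"])
        )
        for _, row in manifest.iterrows()
    ]
    behavior = pd.read_csv(cohort_dir / "behavior.tsv", sep="\t")
    records = [BehavioralRecord(**row) for row in behavior.to_dict(orient="records")]
    return subjects, records


def write_matrix_tsv(matrix: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.8g")
    return path


def write_nifti(volume: np.ndarray, path: str | Path, voxel_size: float = 1.0) -> Path:
    path = Path(path)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))
    return path


def read_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, frozenset):
            return sorted(list(t) for t in o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
    return path
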