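"""End-to-end orchestration of the multilevel correlation analysis.

Runs, in dependency order: cohort simulation (or loading), per-subject
connectivity matrices, edgewise feature detection with jackknife stability,
graph descriptor curves with group comparison, a ReHo phantom group test,
brain-behavior association with demographics, and the ROI FA comparison.
Every randomized stage draws from a seed recorded in the run manifest, and a
rerun with the same configuration reproduces identical output hashes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, edge_stats, graph_metrics, io, reho, roi_anatomy
from .connectivity import connectivity_matrix, group_mean_matrix
from .synthetic_cohort import (
    CohortConfig,
    CoherentRegion,
    RehoPhantomConfig,
    generate_fa_table,
    generate_reho_phantom,
)

DEFAULT_STAGES = ("simulate", "connect", "detect", "graph", "reho", "associate", "fa")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    out_dir: str | Path = "triplenet_run"
    seed: int = 0
    alpha: float = 0.05
    thresholds: tuple[float, ...] = graph_metrics.DEFAULT_THRESHOLDS
    stages: tuple[str, ...] = DEFAULT_STAGES
    cohort: CohortConfig | None = None
    input_dir: str | Path | None = None  # load a cohort instead of simulating
    # ReHo phantom stage parameters (phantoms stand in for real volumes)
    reho_n_per_group: tuple[int, int] = (10, 10)
    reho_grid: tuple[int, int, int] = (12, 12, 12)
    reho_timepoints: int = 40
    reho_permutations: int = 200
    reho_patient_coherence: float = 0.5
    # ROI FA stage
    fa_n_rois: int = 20
    fa_effect: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    manifest: dict = {
        "seed": config.seed,
        "alpha": config.alpha,
        "thresholds": list(config.thresholds),
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, status: str, files: list[Path] | None = None) -> None:
        manifest["stages"][stage] = status
        for f in files or []:
            manifest["outputs"][str(f.relative_to(out))] = _hash_file(f)

    # --- cohort -----------------------------------------------------------
    subjects = records = None
    if config.input_dir is not None:
        subjects, records = io.read_cohort(config.input_dir)
        record("simulate", "loaded")
    elif "simulate" in enabled:
        cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
        from .synthetic_cohort import generate_cohort

        subjects, records = generate_cohort(cohort_cfg)
        cohort_dir = out / "cohort"
        io.write_cohort(subjects, records, cohort_dir)
        record("simulate", "done", sorted(cohort_dir.glob("*.tsv")))
    else:
        record("simulate", "skipped")

    labels = [s.group for s in subjects] if subjects else []

    # --- connectivity -----------------------------------------------------
    matrices = None
    if "connect" in enabled and subjects is not None:
        matrices = [connectivity_matrix(s) for s in subjects]
        files = []
        for grp in sorted(set(labels)):
            mean = group_mean_matrix(matrices, labels, grp)
            path = out / f"group_mean_z_{grp}.tsv"
            pd.DataFrame(mean).to_csv(path, sep="\t", float_format="%.8g")
            files.append(path)
        record("connect", "done", files)
    else:
        record("connect", "skipped")

    # --- edgewise detection + stability ------------------------------------
    feature_set = None
    if "detect" in enabled and matrices is not None:
        table, feature_set = edge_stats.edgewise_test(matrices, labels, config.alpha)
        stability = edge_stats.jackknife_stability(matrices, labels, config.alpha)
        table_path = out / "edge_tests.tsv"
        table.to_csv(table_path, sep="\t", index=False)
        fs_path = io.write_json(
            {
                "feature_set": feature_set.edges,
                "alpha": config.alpha,
                "lambda": stability.lam,
                "n_replicates": stability.n_replicates,
            },
            out / "feature_set.json",
        )
        record("detect", "done", [table_path, fs_path])
    else:
        record("detect", "skipped")

    # --- graph descriptors ---------------------------------------------------
    if "graph" in enabled and matrices is not None:
        curves = []
        curve_labels = []
        for m, g in zip(matrices, labels, strict=True):
            for name in ("clustering", "path_length"):
                curves.append(
                    graph_metrics.descriptor_curve(
                        m.z, config.thresholds, name, subject_id=m.subject_id
                    )
                )
                curve_labels.append(g)
        comparison = graph_metrics.compare_group_descriptors(curves, curve_labels)
        auc_path = out / "descriptor_auc.tsv"
        pd.DataFrame(
            {
                "subject_id": [c.subject_id for c in curves],
                "group": curve_labels,
                "descriptor": [c.descriptor for c in curves],
                "auc": [c.auc for c in curves],
            }
        ).to_csv(auc_path, sep="\t", index=False)
        cmp_path = out / "graph_comparison.tsv"
        comparison.to_csv(cmp_path, sep="\t", index=False)
        record("graph", "done", [auc_path, cmp_path])
    else:
        record("graph", "skipped")

    # --- ReHo phantom group test ---------------------------------------------
    if "reho" in enabled:
        rng_seed = config.seed + 1000
        region = CoherentRegion(
            box=((3, 7), (3, 7), (3, 7)),
            coherence={"patient": config.reho_patient_coherence, "control": 0.0},
        )
        maps = []
        reho_labels = []
        n_pat, n_ctl = config.reho_n_per_group
        for i, grp in enumerate(["patient"] * n_pat + ["control"] * n_ctl):
            cfg = RehoPhantomConfig(
                grid_shape=config.reho_grid,
                timepoints=config.reho_timepoints,
                coherent_regions=[region],
                seed=rng_seed + i,
            )
            vol, mask = generate_reho_phantom(cfg, grp)
            maps.append(reho.standardize_reho(reho.reho_map(vol, mask)))
            reho_labels.append(grp)
        t_map, clusters = reho.reho_group_test(
            maps,
            reho_labels,
            n_permutations=config.reho_permutations,
            seed=config.seed + 2000,
        )
        t_path = io.write_nifti(t_map, out / "reho_tmap.nii.gz")
        cl_path = out / "reho_clusters.tsv"
        pd.DataFrame(
            [
                {"size": c.size, "sign": c.sign, "p_value": c.p_value}
                for c in clusters
            ]
        ).to_csv(cl_path, sep="\t", index=False)
        record("reho", "done", [t_path, cl_path])
    else:
        record("reho", "skipped")

    # --- association -----------------------------------------------------------
    if "associate" in enabled and matrices is not None and records is not None:
        cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
        edge = cohort_cfg.designated_edge
        if feature_set is not None and feature_set.edges:
            edge = sorted(feature_set.edges)[0]
        z_by_subject = {m.subject_id: m.z[edge] for m in matrices}
        pat = [r for r in records if r.group == "patient"]
        assoc = association.feature_behavior_correlation(
            [z_by_subject[r.subject_id] for r in pat], [r.dccs for r in pat]
        )
        reg = association.group_regression(
            [r.dccs for r in records],
            [z_by_subject[r.subject_id] for r in records],
            [r.group for r in records],
        )
        demo = association.demographics_table(records)
        assoc_path = io.write_json(
            {
                "edge": list(edge),
                "pearson_r": assoc.r,
                "p": assoc.p,
                "n": assoc.n,
                "normality_p": assoc.normality_p,
                "regression": reg.terms.to_dict(orient="records"),
                "r_squared": reg.r_squared,
            },
            out / "association.json",
        )
        demo_path = out / "demographics.tsv"
        demo.to_csv(demo_path, sep="\t", index=False)
        record("associate", "done", [assoc_path, demo_path])
    else:
        record("associate", "skipped")

    # --- ROI FA -----------------------------------------------------------------
    if "fa" in enabled:
        fa_table = generate_fa_table(
            n_rois=config.fa_n_rois, effect=config.fa_effect, seed=config.seed + 3000
        )
        result = roi_anatomy.roi_group_test(fa_table, config.alpha)
        fa_path = out / "fa_roi_tests.tsv"
        result.to_csv(fa_path, sep="\t", index=False)
        record("fa", "done", [fa_path])
    else:
        record("fa", "skipped")

    io.write_json(manifest, out / "manifest.json")
    return manifest
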