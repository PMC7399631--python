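"""Synthetic cohorts with the statistical structure of a triple-network study.

The generator emulates a resting-state study of mild traumatic brain injury:
32 patients and 37 matched controls, each described by seven ICA component
time courses (four default-mode, one salience, two central-executive
components), an executive-function scale score (DCCS, normed to mean 100 and
SD 15), and per-tract white-matter FA summaries.  One designated DMN-SN edge
carries an elevated population Fisher-Z coupling in patients (control mean
0.037, SD 0.22; patient mean 0.201, SD 0.18), and within patients the DCCS
score co-varies with that edge (Gaussian-copula correlation, default 0.40).

Subject heterogeneity is injected in Fisher-Z space and mapped through tanh,
which keeps every subject-level correlation inside (-1, 1).  When the edge
substitution breaks positive semidefiniteness the target matrix is repaired
by nearest-correlation-matrix projection (eigenvalue clipping with
unit-diagonal restoration) while re-imposing the designated edge value.
Finite-length time series add ~1/sqrt(T) sampling noise on top of the
configured between-subject SD; this mirrors real estimation noise and is the
intended behaviour, not a bug.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest

NETWORKS = ("DMN", "SN", "CEN")

#: default qualitative coupling pattern: positive within-network coupling,
#: DMN anticorrelated with both task-positive networks, weak SN-CEN coupling.
WITHIN_COUPLING = 0.4
DMN_TASK_COUPLING = -0.2
SN_CEN_COUPLING = 0.1


def default_network_assignment(n_components: int = 7) -> dict[int, str]:
    """4 DMN + 1 SN + 2 CEN components, the study's triple-network graph."""
    if n_components != 7:
        raise ValueError("the default assignment is defined for 7 components")
    return {0: "DMN", 1: "DMN", 2: "DMN", 3: "DMN", 4: "SN", 5: "CEN", 6: "CEN"}


def default_coupling_template(assignment: dict[int, str]) -> np.ndarray:
    """Symmetric unit-diagonal population correlation template."""
    k = len(assignment)
    template = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = assignment[i], assignment[j]
            if a == b:
                v = WITHIN_COUPLING
            elif {a, b} == {"SN", "CEN"}:
                v = SN_CEN_COUPLING
            else:  # DMN vs SN or DMN vs CEN
                v = DMN_TASK_COUPLING
            template[i, j] = template[j, i] = v
    return template


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the emulated study: group sizes 32/37, seven
    components over 200 timepoints at TR = 1.5 s, the designated DMN-SN edge
    with group Fisher-Z means 0.201/0.037 (SDs 0.18/0.22), DCCS group means
    98/103 (SDs 12.8/10.9) and a within-patient edge-DCCS correlation of 0.40.
    """

    n_patients: int = 32
    n_controls: int = 37
    n_components: int = 7
    network_assignment: dict[int, str] | None = None
    timepoints: int = 200
    tr: float = 1.5
    base_coupling_template: np.ndarray | None = None
    designated_edge: tuple[int, int] = (0, 4)
    edge_z_mean_control: float = 0.037
    edge_z_sd_control: float = 0.22
    edge_z_mean_patient: float = 0.201
    edge_z_sd_patient: float = 0.18
    dccs_mean_control: float = 103.0
    dccs_sd_control: float = 10.9
    dccs_mean_patient: float = 98.0
    dccs_sd_patient: float = 12.8
    dccs_edge_correlation: float = 0.40
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.network_assignment is None:
            self.network_assignment = default_network_assignment(self.n_components)
        if self.base_coupling_template is None:
            self.base_coupling_template = default_coupling_template(
                self.network_assignment
            )
        self.validate()

    def validate(self) -> None:
        if min(self.n_patients, self.n_controls, self.n_components, self.timepoints) <= 0:
            raise ValueError("counts must be positive")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        for sd in (
            self.edge_z_sd_control,
            self.edge_z_sd_patient,
            self.dccs_sd_control,
            self.dccs_sd_patient,
        ):
            if sd < 0:
                raise ValueError("SDs must be nonnegative")
        i, j = self.designated_edge
        if i == j or not (0 <= i < self.n_components and 0 <= j < self.n_components):
            raise ValueError("designated_edge must be an off-diagonal component pair")
        tpl = np.asarray(self.base_coupling_template, dtype=float)
        if tpl.shape != (self.n_components, self.n_components):
            raise ValueError("template shape must match n_components")
        if not np.allclose(tpl, tpl.T):
            raise ValueError("template must be symmetric")
        if not np.allclose(np.diag(tpl), 1.0):
            raise ValueError("template must have unit diagonal")
        off = tpl[~np.eye(self.n_components, dtype=bool)]
        if np.any(np.abs(off) >= 1.0):
            raise ValueError("template off-diagonal entries must lie in (-1, 1)")
        if abs(self.dccs_edge_correlation) >= 1.0:
            raise ValueError("|dccs_edge_correlation| must be < 1")
        if set(self.network_assignment.values()) - set(NETWORKS):
            raise ValueError(f"network labels must be in {NETWORKS}")

    def component_labels(self) -> list[tuple[str, str]]:
        return [
            (f"c{i}", self.network_assignment[i]) for i in range(self.n_components)
        ]


@dataclass
class ComponentTimeSeriesSet:
    """One subject's K x T component time courses."""

    subject_id: str
    group: str
    series: np.ndarray
    tr: float
    component_labels: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class BehavioralRecord:
    """Per-subject behavioral and demographic record."""

    subject_id: str
    group: str
    dccs: float
    bsi18: float
    age: float
    sex: str
    education: float


def project_to_correlation(
    target: np.ndarray,
    edge: tuple[int, int],
    edge_value: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Nearest valid correlation matrix that preserves the designated edge.

    Alternates nearest-correlation projection (eigenvalue clipping with
    unit-diagonal restoration) with re-imposition of the designated edge.
    Raises if no valid matrix is reached within tolerance.
    """
    i, j = edge
    m = np.asarray(target, dtype=float).copy()
    for _ in range(max_iter):
        m[i, j] = m[j, i] = edge_value
        eigvals = np.linalg.eigvalsh(m)
        if eigvals[0] >= -tol:
            return m
        with warnings.catch_warnings():
            # convergence is verified by the eigenvalue check above
            warnings.simplefilter("ignore")
            m = corr_nearest(m, threshold=tol / 10, n_fact=100)
    raise ValueError(
        "no valid correlation matrix preserving the designated edge "
        f"was found within tolerance {tol}"
    )


def _sampling_factor(corr: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Matrix square root via eigendecomposition with tiny-negative clipping."""
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals[0] < -tol:
        raise ValueError("matrix failed the positive-semidefiniteness check")
    return eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[ComponentTimeSeriesSet], list[BehavioralRecord]]:
    """Simulate component time courses and behavior for a full cohort.

    For each subject a target correlation matrix is built from the coupling
    template with the designated edge replaced by tanh of a Fisher-Z draw
    from the subject's group distribution; T multivariate-normal timepoints
    are then sampled from it.  Patient DCCS is tied to the subject's edge-Z
    draw through a Gaussian copula with the configured correlation.
    """
    rng = np.random.default_rng(config.seed)
    labels = config.component_labels()
    k, t = config.n_components, config.timepoints
    subjects: list[ComponentTimeSeriesSet] = []
    records: list[BehavioralRecord] = []

    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    for idx, group in enumerate(groups):
        sid = f"sub-{idx + 1:03d}"
        if group == "patient":
            mu, sd = config.edge_z_mean_patient, config.edge_z_sd_patient
        else:
            mu, sd = config.edge_z_mean_control, config.edge_z_sd_control
        z_edge = rng.normal(mu, sd)
        target = project_to_correlation(
            config.base_coupling_template, config.designated_edge, np.tanh(z_edge)
        )
        factor = _sampling_factor(target)
        series = factor @ rng.standard_normal((k, t))
        subjects.append(
            ComponentTimeSeriesSet(
                subject_id=sid,
                group=group,
                series=series,
                tr=config.tr,
                component_labels=labels,
            )
        )
        records.append(
            _behavioral_record(sid, group, z_edge, mu, sd, config, rng)
        )
    return subjects, records


def _behavioral_record(
    sid: str,
    group: str,
    z_edge: float,
    edge_mu: float,
    edge_sd: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> BehavioralRecord:
    rho = config.dccs_edge_correlation
    if group == "patient":
        # Gaussian copula: the DCCS latent shares the edge draw's standard
        # normal score with weight rho (within patients only).
        u = (z_edge - edge_mu) / edge_sd if edge_sd > 0 else rng.standard_normal()
        latent = rho * u + np.sqrt(1.0 - rho**2) * rng.standard_normal()
        dccs = config.dccs_mean_patient + config.dccs_sd_patient * latent
        bsi18 = max(0.0, rng.normal(15.0, 14.4))
        age = rng.normal(30.0, 6.0)
        education = rng.normal(15.0, 2.2)
        p_female = 12 / 32
    else:
        dccs = rng.normal(config.dccs_mean_control, config.dccs_sd_control)
        bsi18 = max(0.0, rng.normal(2.0, 2.0))
        age = rng.normal(31.0, 8.7)
        education = rng.normal(16.0, 2.2)
        p_female = 16 / 37
    sex = "female" if rng.random() < p_female else "male"
    return BehavioralRecord(
        subject_id=sid,
        group=group,
        dccs=float(dccs),
        bsi18=float(bsi18),
        age=float(age),
        sex=sex,
        education=float(education),
    )


def generate_normative_dccs(
    n: int, seed: int | None = None, mean: float = 100.0, sd: float = 15.0
) -> np.ndarray:
    """DCCS scale scores under the instrument's norming convention.

    The scale score is normed to mean 100 and SD 15 in the healthy reference
    population; this draws n scores from that normative distribution.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    return np.random.default_rng(seed).normal(mean, sd, n)


# ---------------------------------------------------------------------------
# ReHo phantom volumes


@dataclass
class CoherentRegion:
    """Axis-aligned voxel box sharing a latent time series.

    ``coherence`` is either a single level in [0, 1] or a per-group mapping,
    allowing group-specific local synchrony.
    """

    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    coherence: float | dict[str, float]

    def level(self, group: str) -> float:
        c = self.coherence[group] if isinstance(self.coherence, dict) else self.coherence
        if not 0.0 <= c <= 1.0:
            raise ValueError("coherence must lie in [0, 1]")
        return float(c)


@dataclass
class RehoPhantomConfig:
    """Configuration of a small synthetic 4D volume for local-connectivity tests."""

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    timepoints: int = 60
    coherent_regions: list[CoherentRegion] = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for region in self.coherent_regions:
            for (lo, hi), n in zip(region.box, self.grid_shape, strict=True):
                if not (0 <= lo < hi <= n):
                    raise ValueError(f"region box {region.box} outside grid")


def generate_reho_phantom(
    config: RehoPhantomConfig, group: str = "control"
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic 4D volume plus brain mask.

    Voxels inside a coherent region share a latent time series scaled by the
    region's coherence level, plus independent Gaussian noise; voxels outside
    any region carry independent noise only.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    t = config.timepoints
    volume = config.noise_sd * rng.standard_normal(shape + (t,))
    for region in config.coherent_regions:
        latent = rng.standard_normal(t)
        (x0, x1), (y0, y1), (z0, z1) = region.box
        volume[x0:x1, y0:y1, z0:z1, :] += region.level(group) * latent
    mask = np.ones(shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty phantom mask")
    return volume, mask


# ---------------------------------------------------------------------------
# ROI FA tables


def generate_fa_table(
    n_per_group: tuple[int, int] = (32, 37),
    n_rois: int = 20,
    effect: float = 0.0,
    seed: int | None = None,
    designated_rois: tuple[int, ...] = (0,),
    noise_sd: float = 0.04,
) -> pd.DataFrame:
    """Per-subject, per-ROI mean FA values with an optional group effect.

    Each ROI has a tract-specific baseline FA; patients receive ``effect``
    added on the designated ROIs.  The default effect of zero emulates a null
    anatomical finding.  FA values escaping (0, 1) are clipped with a warning.
    """
    if n_rois < 1:
        raise ValueError("need at least one ROI")
    n_patients, n_controls = n_per_group
    rng = np.random.default_rng(seed)
    roi_base = rng.uniform(0.35, 0.65, n_rois)
    rows = []
    groups = ["patient"] * n_patients + ["control"] * n_controls
    for idx, group in enumerate(groups):
        fa = roi_base + rng.normal(0.0, noise_sd, n_rois)
        if group == "patient" and effect != 0.0:
            fa[list(designated_rois)] += effect
        if np.any((fa <= 0.0) | (fa >= 1.0)):
            warnings.warn("FA outside (0, 1); clipping", RuntimeWarning, stacklevel=2)
            fa = np.clip(fa, 1e-6, 1.0 - 1e-6)
        for roi in range(n_rois):
            rows.append(
                {
                    "subject_id": f"sub-{idx + 1:03d}",
                    "group": group,
                    "roi_id": f"roi-{roi:02d}",
                    "mean_fa": float(fa[roi]),
                }
            )
    return pd.DataFrame(rows)
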