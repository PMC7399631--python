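"""Component correlation analysis: edgewise rank-sum group tests, BH FDR,
feature-set extraction, and leave-one-out (jackknife) stability.

Every unordered off-diagonal edge of the K x K Fisher-Z matrix is compared
between groups with the Wilcoxon rank-sum test; Benjamini-Hochberg correction
is applied jointly across all K(K-1)/2 edges of the tested graph.  Edges with
adjusted p < alpha form the detected feature set F.  Stability is the
fraction of leave-one-subject-out reruns whose feature set is identical
(strict set equality) to the original: lambda = N_[original=resampling] / n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix

#: both samples at or below this size (and tie-free) use exact enumeration
EXACT_N_MAX = 12


@dataclass
class FeatureSet:
    """Edges whose FDR-adjusted p-value falls below alpha."""

    edges: frozenset[tuple[int, int]]
    alpha: float = 0.05

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FeatureSet) and self.edges == other.edges


@dataclass
class StabilityResult:
    """Jackknife stability of the detected feature set."""

    lam: float
    n_replicates: int
    replicate_sets: list[FeatureSet] = field(default_factory=list)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses exact enumeration when both samples have at most 12 observations and
    no ties are present; otherwise the normal approximation with tie-corrected
    variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= EXACT_N_MAX and y.size <= EXACT_N_MAX and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _edge_array(matrices: list[ConnectivityMatrix]) -> tuple[np.ndarray, list[tuple[int, int]]]:
    k = matrices[0].n_components
    edges = [(i, j) for i in range(k) for j in range(i + 1, k)]
    values = np.array([[m.z[i, j] for (i, j) in edges] for m in matrices])
    return values, edges


def edgewise_test(
    matrices: list[ConnectivityMatrix],
    labels: list[str],
    alpha: float = 0.05,
    patient_label: str = "patient",
) -> tuple[pd.DataFrame, FeatureSet]:
    """Wilcoxon rank-sum per edge with joint BH correction.

    Returns the edge test table (one row per unordered off-diagonal pair)
    and the detected feature set (edges with adjusted p < alpha).
    """
    labels = list(labels)
    is_patient = np.array([lab == patient_label for lab in labels])
    if is_patient.sum() < 2 or (~is_patient).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    ks = {m.n_components for m in matrices}
    if len(ks) != 1:
        raise ValueError("inconsistent matrix sizes")
    values, edges = _edge_array(matrices)
    pat, ctl = values[is_patient], values[~is_patient]
    p_raw = np.array([wilcoxon_rank_sum(pat[:, e], ctl[:, e]) for e in range(len(edges))])
    p_adj = bh_fdr(p_raw)
    mean_pat = pat.mean(axis=0)
    mean_ctl = ctl.mean(axis=0)
    table = pd.DataFrame(
        {
            "edge": edges,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": np.sign(mean_pat - mean_ctl).astype(int),
            "mean_control": mean_ctl,
            "mean_patient": mean_pat,
        }
    )
    feature_set = FeatureSet(
        edges=frozenset(e for e, p in zip(edges, p_adj) if p < alpha), alpha=alpha
    )
    return table, feature_set


def jackknife_stability(
    matrices: list[ConnectivityMatrix],
    labels: list[str],
    alpha: float = 0.05,
    patient_label: str = "patient",
) -> StabilityResult:
    """Leave-one-subject-out stability of the detected feature set.

    Each of the n replicates drops one subject and reruns the edgewise
    analysis; lambda is the fraction of replicate feature sets identical to
    the original.  Near-miss overlap is not counted — equality is strict.
    """
    labels = list(labels)
    n = len(matrices)
    counts = {lab: labels.count(lab) for lab in set(labels)}
    if any(c < 3 for c in counts.values()):
        raise ValueError("need at least 3 subjects per group for the jackknife")
    _, original = edgewise_test(matrices, labels, alpha, patient_label)
    replicate_sets: list[FeatureSet] = []
    agree = 0
    for drop in range(n):
        sub_m = matrices[:drop] + matrices[drop + 1 :]
        sub_l = labels[:drop] + labels[drop + 1 :]
        _, fs = edgewise_test(sub_m, sub_l, alpha, patient_label)
        replicate_sets.append(fs)
        agree += fs.edges == original.edges
    return StabilityResult(lam=agree / n, n_replicates=n, replicate_sets=replicate_sets)
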