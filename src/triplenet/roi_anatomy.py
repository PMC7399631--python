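"""ROI-level anatomical connectivity comparison.

Per-tract mean fractional anisotropy (FA) values are compared between groups
with the Mann-Whitney U test (the same rank-sum engine as the edgewise
connectivity tests) and corrected across ROIs with Benjamini-Hochberg FDR.
Voxelwise skeleton-based statistics are out of scope; this is the tabular
ROI path only, with ROI identities supplied by the caller.
"""

from __future__ import annotations

import pandas as pd

from .edge_stats import bh_fdr, wilcoxon_rank_sum

REQUIRED_COLUMNS = ("subject_id", "group", "roi_id", "mean_fa")


def roi_group_test(
    table: pd.DataFrame,
    alpha: float = 0.05,
    patient_label: str = "patient",
) -> pd.DataFrame:
    """Mann-Whitney U per ROI with BH correction across ROIs.

    ``table`` is long-format with columns subject_id, group, roi_id, mean_fa
    and a complete subject x ROI grid.  Returns one row per ROI with raw and
    adjusted p-values and a significance flag at ``alpha``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    counts = table.groupby("subject_id")["roi_id"].nunique()
    n_rois = table["roi_id"].nunique()
    incomplete = counts[counts != n_rois]
    if not incomplete.empty:
        raise ValueError(
            f"incomplete subject x ROI grid for subjects: {list(incomplete.index)}"
        )
    rows = []
    for roi, sub in table.groupby("roi_id", sort=True):
        pat = sub.loc[sub["group"] == patient_label, "mean_fa"].to_numpy()
        ctl = sub.loc[sub["group"] != patient_label, "mean_fa"].to_numpy()
        if len(pat) < 2 or len(ctl) < 2:
            raise ValueError(f"ROI {roi!r} needs at least 2 subjects per group")
        rows.append({"roi_id": roi, "p_raw": wilcoxon_rank_sum(pat, ctl)})
    result = pd.DataFrame(rows)
    result["p_adj"] = bh_fdr(result["p_raw"].to_numpy())
    result["significant"] = result["p_adj"] < alpha
    return result
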