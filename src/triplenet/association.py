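"""Brain-behavior association and cohort demographics.

Associates the detected connectivity feature with executive function (DCCS
scale score): Pearson correlation within patients, OLS regression over all
subjects with group membership and an optional feature-by-group interaction,
plus a demographics table (t-tests for continuous variables, Yates-corrected
chi-square for the sex ratio).  The feature-DCCS p-value is deliberately not
adjusted for the other tasks of the cognitive battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic_cohort import BehavioralRecord


@dataclass
class AssociationResult:
    r: float
    p: float
    n: int
    normality_p: dict[str, float]


@dataclass
class RegressionResult:
    terms: pd.DataFrame  # name, coef, se, t, p
    r_squared: float
    n: int


def feature_behavior_correlation(feature_values, scores) -> AssociationResult:
    """Pearson correlation between a connectivity feature and DCCS scores.

    Shapiro-Wilk normality p-values are attached for each variable as a
    diagnostic; they do not alter the correlation test.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant vector has undefined correlation")
    r, p = stats.pearsonr(x, y)
    normality = {
        "feature": float(stats.shapiro(x).pvalue),
        "score": float(stats.shapiro(y).pvalue),
    }
    return AssociationResult(r=float(r), p=float(p), n=int(x.size), normality_p=normality)


def group_regression(
    scores,
    feature_values,
    groups=None,
    covariates: dict[str, np.ndarray] | None = None,
    include_interaction: bool = False,
    patient_label: str = "patient",
) -> RegressionResult:
    """OLS of DCCS on the feature, group membership, and optional covariates.

    Group is coded 0 = control, 1 = patient.  With ``include_interaction`` a
    feature-by-group product term is added.  ``groups=None`` fits a
    within-group model (e.g. DCCS ~ feature + severity within patients).
    """
    y = np.asarray(scores, dtype=float)
    x = np.asarray(feature_values, dtype=float)
    cols: dict[str, np.ndarray] = {"feature": x}
    if groups is not None:
        g = np.array([1.0 if lab == patient_label else 0.0 for lab in groups])
        cols["group"] = g
        if include_interaction:
            cols["feature:group"] = x * g
    elif include_interaction:
        raise ValueError("interaction requires group membership")
    for name, values in (covariates or {}).items():
        cols[name] = np.asarray(values, dtype=float)
    design = pd.DataFrame(cols)
    design.insert(0, "intercept", 1.0)
    if y.size <= design.shape[1] + 2:
        raise ValueError("too few observations for the requested model")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        aliased = [
            c
            for i, c in enumerate(design.columns)
            if np.linalg.matrix_rank(design.drop(columns=c).to_numpy()) == rank
        ]
        raise ValueError(f"rank-deficient design (aliased terms: {aliased})")
    fit = sm.OLS(y, design).fit()
    terms = pd.DataFrame(
        {
            "term": design.columns,
            "coef": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    return RegressionResult(terms=terms, r_squared=float(fit.rsquared), n=int(y.size))


def yates_chi_square(table: np.ndarray) -> tuple[float, float]:
    """Chi-square test on a 2x2 table with Yates continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def demographics_table(
    records: list[BehavioralRecord],
    welch: bool = False,
    patient_label: str = "patient",
) -> pd.DataFrame:
    """Group comparison of age, education, DCCS (t-test) and sex (chi-square).

    Continuous rows report mean (SD) per group with a pooled-variance
    two-sample t-test p-value; the sex ratio uses a Yates-corrected 2x2
    chi-square.
    """
    pat = [r for r in records if r.group == patient_label]
    ctl = [r for r in records if r.group != patient_label]
    if not pat or not ctl:
        raise ValueError("both groups must be nonempty")
    if len(pat) < 2 or len(ctl) < 2:
        raise ValueError("t-tests need at least 2 subjects per group")
    rows = []
    for name in ("age", "education", "dccs"):
        a = np.array([getattr(r, name) for r in pat])
        b = np.array([getattr(r, name) for r in ctl])
        if a.std() == 0 and b.std() == 0 and np.allclose(a.mean(), b.mean()):
            p = 1.0
        else:
            _, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            {
                "variable": name,
                "patient": f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
                "control": f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
                "p": float(p),
            }
        )
    counts = np.array(
        [
            [sum(r.sex == "female" for r in pat), sum(r.sex == "male" for r in pat)],
            [sum(r.sex == "female" for r in ctl), sum(r.sex == "male" for r in ctl)],
        ]
    )
    if counts.min() >= 0 and counts.sum(axis=1).min() > 0:
        _, p_sex = yates_chi_square(counts)
    else:  # degenerate table
        p_sex = float("nan")
    rows.append(
        {
            "variable": "sex (female/male)",
            "patient": f"{counts[0, 0]}/{counts[0, 1]}",
            "control": f"{counts[1, 0]}/{counts[1, 1]}",
            "p": p_sex,
        }
    )
    return pd.DataFrame(rows)
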