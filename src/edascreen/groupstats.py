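"""Nonparametric group statistics for the five-phase cohort design.

Electrodermal features are heavily skewed, so group comparisons avoid
normality assumptions throughout: Mann-Whitney U for two-group contrasts,
Pearson chi-square for categorical factors, a rank-based ANOVA-type
statistic (ATS) for the group x task factorial with repeated measures, and
Benjamini-Hochberg control of the false discovery rate across features.

The ATS follows Brunner's methodology for the two-factor design with one
whole-plot factor (group) and one repeated factor (task): all observations
are mid-ranked together, cell means of the ranks estimate relative
treatment effects, and the quadratic form of the hypothesis projection is
referred to an F distribution with Box-approximated numerator degrees of
freedom.  The within-subject hypotheses (task, interaction) use an infinite
denominator df; the group effect uses a Box-type denominator df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sigproc import PHASE_NAMES


@dataclass
class TestResult:
    statistic: float
    p_value: float
    effect: str
    df: tuple[float, float] | float | None = None
    p_adjusted: float | None = None


def mann_whitney_u(sample_a, sample_b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution for small tie-free samples
    (n_a + n_b <= 12), and the normal approximation with tie and continuity
    corrections otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) + len(b) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue), "U")


def chi_square_test(contingency, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x k count table."""
    table = np.asarray(contingency, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(table, correction=yates)
    return TestResult(float(res.statistic), float(res.pvalue), "chi2", df=float(res.dof))


def _hypothesis_projections(a: int, t: int) -> dict[str, np.ndarray]:
    Pa = np.eye(a) - np.full((a, a), 1.0 / a)
    Pt = np.eye(t) - np.full((t, t), 1.0 / t)
    Ja = np.full((a, a), 1.0 / a)
    Jt = np.full((t, t), 1.0 / t)
    return {
        "group": np.kron(Pa, Jt),
        "task": np.kron(Ja, Pt),
        "interaction": np.kron(Pa, Pt),
    }


def ats_group_task(panel: pd.DataFrame) -> dict[str, TestResult]:
    """ANOVA-type statistics for the group (between) x task (within) design.

    ``panel`` is long-format with columns ``subject_id``, ``group``,
    ``task`` and ``value``; every subject must contribute exactly one value
    per task level.  Returns results for the group main effect, the task
    main effect and their interaction.
    """
    required = {"subject_id", "group", "task", "value"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    groups = sorted(panel["group"].unique())
    tasks = [t for t in PHASE_NAMES if t in set(panel["task"])] or sorted(
        panel["task"].unique()
    )
    a, t = len(groups), len(tasks)
    if a != 2:
        raise ValueError(f"expected two groups, got {groups}")

    # subjects x tasks rank matrix, grouped
    wide = panel.pivot_table(index=["group", "subject_id"], columns="task",
                             values="value", aggfunc="first")
    wide = wide.reindex(columns=tasks)
    if wide.isna().any().any():
        raise ValueError("panel is incomplete: every subject needs every task level")

    values = wide.to_numpy()
    m_total = values.size
    ranks = stats.rankdata(values, method="average").reshape(values.shape)

    group_index = wide.index.get_level_values("group")
    n_i = np.array([int((group_index == g).sum()) for g in groups])
    if (n_i < 2).any():
        raise ValueError("each group needs at least two subjects")

    # relative effects and block-diagonal covariance of their estimates
    p_hat = np.empty(a * t)
    cov = np.zeros((a * t, a * t))
    for i, g in enumerate(groups):
        block = ranks[group_index == g]  # n_i x t
        p_hat[i * t : (i + 1) * t] = (block.mean(axis=0) - 0.5) / m_total
        S = np.cov(block, rowvar=False, ddof=1)
        cov[i * t : (i + 1) * t, i * t : (i + 1) * t] = S / (n_i[i] * m_total**2)

    out: dict[str, TestResult] = {}
    for name, M in _hypothesis_projections(a, t).items():
        MV = M @ cov
        tr_mv = float(np.trace(MV))
        stat = float(p_hat @ M @ p_hat) / tr_mv
        f1 = tr_mv**2 / float(np.trace(MV @ MV))
        if name == "group":
            denom = 0.0
            for i in range(a):
                sl = slice(i * t, (i + 1) * t)
                denom += float(np.trace(M[sl, sl] @ cov[sl, sl])) ** 2 / (n_i[i] - 1)
            f0 = tr_mv**2 / denom
            p = float(stats.f.sf(stat, f1, f0))
            df = (f1, f0)
        else:
            p = float(stats.chi2.sf(stat * f1, f1))  # F(f1, inf)
            df = (f1, np.inf)
        out[name] = TestResult(stat, p, "ATS", df=df)
    return out


def bh_fdr(p_values, level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, rejection flags at ``level``).  Adjusted
    values are p(i) * m / i with enforced monotonicity, in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return p_adj, reject


def feature_stats_report(table: pd.DataFrame, level: float = 0.05) -> pd.DataFrame:
    """Per-feature group comparison across the whole feature table.

    Each of the 36 features is compared between groups with a two-sided
    Mann-Whitney U test; p-values are BH-adjusted jointly.  Returns a frame
    with columns feature, statistic, p_value, p_adjusted, significant.
    """
    feature_cols = [c for c in table.columns if c not in ("subject_id", "group")]
    ctrl = table[table["group"] == "control"]
    case = table[table["group"] == "case"]
    rows = []
    for col in feature_cols:
        res = mann_whitney_u(ctrl[col].to_numpy(), case[col].to_numpy())
        rows.append({"feature": col, "statistic": res.statistic, "p_value": res.p_value})
    report = pd.DataFrame(rows)
    p_adj, reject = bh_fdr(report["p_value"].to_numpy(), level)
    report["p_adjusted"] = p_adj
    report["significant"] = reject
    return report


def ats_report(table: pd.DataFrame) -> pd.DataFrame:
    """Group x task ATS for each base feature, using the five primary sets
    as the within-subject task levels; p-values BH-adjusted per hypothesis."""
    from .featureset import BASE_FEATURES, PRIMARY_SETS

    rows = []
    for feat in BASE_FEATURES:
        records = []
        for pset, phase in PRIMARY_SETS.items():
            col = f"{pset}_{feat}"
            for _, r in table.iterrows():
                records.append(
                    {
                        "subject_id": r["subject_id"],
                        "group": r["group"],
                        "task": phase,
                        "value": r[col],
                    }
                )
        results = ats_group_task(pd.DataFrame.from_records(records))
        for hyp, res in results.items():
            rows.append(
                {
                    "feature": feat,
                    "hypothesis": hyp,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
    report = pd.DataFrame(rows)
    for hyp in report["hypothesis"].unique():
        sel = report["hypothesis"] == hyp
        p_adj, reject = bh_fdr(report.loc[sel, "p_value"].to_numpy())
        report.loc[sel, "p_adjusted"] = p_adj
        report.loc[sel, "significant"] = reject
    return report
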