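"""Statistical characterisation of mounting-phenotype clusters.

Per-cluster summaries, sex-by-cluster association (Pearson chi-square and
Cramer's V), one-way ANOVA with Tukey(-Kramer) HSD post hoc comparisons, the
all-pairs-significant variable-selection rule, Mann-Whitney U comparisons,
and the comparison of derived Bonwill-arm / Balkwill-angle values against
their articulator norms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import BALKWILL_NORM_RANGE_DEG, BONWILL_NORM_MM

__all__ = [
    "ClusterSummary",
    "ContingencyResult",
    "TukeyResult",
    "MannWhitneyResult",
    "summarize_clusters",
    "chi_square_cramers_v",
    "anova_tukey",
    "select_discriminative_variables",
    "mann_whitney",
    "bonwill_balkwill_report",
]


@dataclass(frozen=True)
class ClusterSummary:
    """Per-cluster n/mean/SD tables plus sex counts and age-by-sex summaries."""

    variables: pd.DataFrame  # index (cluster, variable), columns n/mean/sd
    sex_counts: pd.DataFrame  # index cluster, columns female/male
    age_by_sex: pd.DataFrame  # index (cluster, sex), columns n/mean/sd


@dataclass(frozen=True)
class ContingencyResult:
    observed: np.ndarray
    chi_square: float
    df: int
    p_value: float
    cramers_v: float


@dataclass(frozen=True)
class TukeyResult:
    f_statistic: float
    anova_p: float
    pairs: list[tuple[tuple[int, int], float, float]]  # ((i, j), meandiff, p_adj)
    all_pairs_significant: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    z: float
    p_value: float


def _mean_sd(x: np.ndarray) -> tuple[int, float, float]:
    x = np.asarray(x, dtype=float)
    n = len(x)
    return n, float(np.mean(x)), float(np.std(x, ddof=1)) if n > 1 else float("nan")


def summarize_clusters(
    cohort: pd.DataFrame,
    assignments: np.ndarray,
    variables: list[str],
) -> ClusterSummary:
    """Arithmetic mean and n-1 SD per cluster and variable, plus sex/age."""
    assignments = np.asarray(assignments)
    if len(assignments) != len(cohort):
        raise ValueError("assignments must match cohort length")
    clusters = sorted(set(int(a) for a in assignments))
    rows = []
    for c in clusters:
        sub = cohort.loc[assignments == c]
        if len(sub) == 0:
            raise ValueError(f"cluster {c} is empty")
        for v in variables:
            n, m, sd = _mean_sd(sub[v].to_numpy())
            rows.append({"cluster": c, "variable": v, "n": n, "mean": m, "sd": sd})
    var_tab = pd.DataFrame(rows).set_index(["cluster", "variable"])

    sex_rows, age_rows = [], []
    for c in clusters:
        sub = cohort.loc[assignments == c]
        counts = {"female": 0, "male": 0}
        if "sex" in cohort.columns:
            vc = sub["sex"].value_counts()
            counts = {"female": int(vc.get("female", 0)), "male": int(vc.get("male", 0))}
            if "age" in cohort.columns:
                for sex in ("female", "male"):
                    grp = sub.loc[sub["sex"] == sex, "age"]
                    if len(grp):
                        n, m, sd = _mean_sd(grp.to_numpy())
                        age_rows.append(
                            {"cluster": c, "sex": sex, "n": n, "mean": m, "sd": sd}
                        )
        sex_rows.append({"cluster": c, **counts})
    sex_tab = pd.DataFrame(sex_rows).set_index("cluster")
    age_tab = (
        pd.DataFrame(age_rows).set_index(["cluster", "sex"])
        if age_rows
        else pd.DataFrame(columns=["n", "mean", "sd"])
    )
    return ClusterSummary(variables=var_tab, sex_counts=sex_tab, age_by_sex=age_tab)


def chi_square_cramers_v(table) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) and Cramer's V.

    V = sqrt(chi2 / (n * (min(rows, cols) - 1))).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2D")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    n = obs.sum()
    v = math.sqrt(chi2 / (n * (min(obs.shape) - 1)))
    return ContingencyResult(
        observed=obs.astype(int),
        chi_square=float(chi2),
        df=int(df),
        p_value=float(p),
        cramers_v=float(v),
    )


def anova_tukey(groups: list[np.ndarray], alpha: float = 0.05) -> TukeyResult:
    """One-way ANOVA with Tukey HSD post hoc pairwise comparisons.

    Unequal group sizes use the Tukey-Kramer correction (studentized-range
    distribution).  ``all_pairs_significant`` flags adjusted p < alpha for
    every pair.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    if all(np.var(g) == 0 for g in groups):
        raise ValueError("zero within-group variance in every group")
    f, p = sps.f_oneway(*groups)
    hsd = sps.tukey_hsd(*groups)
    pairs = []
    k = len(groups)
    for i in range(k):
        for j in range(i + 1, k):
            pairs.append(
                (
                    (i, j),
                    float(np.mean(groups[i]) - np.mean(groups[j])),
                    float(hsd.pvalue[i, j]),
                )
            )
    all_sig = all(p_adj < alpha for _, _, p_adj in pairs)
    return TukeyResult(
        f_statistic=float(f),
        anova_p=float(p),
        pairs=pairs,
        all_pairs_significant=all_sig,
        alpha=alpha,
    )


def select_discriminative_variables(
    tukey_by_variable: dict[str, TukeyResult], alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Keep a variable iff every pairwise adjusted p is below alpha.

    Variables separating only two of the three clusters are excluded.
    """
    kept, excluded = [], []
    for name, res in tukey_by_variable.items():
        (kept if all(p < alpha for _, _, p in res.pairs) else excluded).append(name)
    return kept, excluded


def mann_whitney(a, b) -> MannWhitneyResult:
    """Mann-Whitney U with mid-rank ties and the normal approximation.

    U is the statistic of the first group; z carries a tie-corrected SD and
    a 0.5 continuity correction.  Identical pooled samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return MannWhitneyResult(u=float(u), z=0.0, p_value=1.0)
    diff = u - mu
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    z = (diff - cc) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return MannWhitneyResult(u=float(u), z=float(z), p_value=float(min(p, 1.0)))


def bonwill_balkwill_report(
    derived: pd.DataFrame,
    assignments: np.ndarray,
    labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-cluster Ie-Ax / Balkwill means vs. the articulator norms.

    ``derived`` needs per-patient ``ie_ax_mm`` and ``balkwill_deg`` columns.
    Flags whether the cluster-mean Balkwill angle falls inside the 18-25
    degree norm range and reports the deviation of the mean Ie-Ax from the
    101.6 mm Bonwill norm arm.
    """
    assignments = np.asarray(assignments)
    clusters = sorted(set(int(a) for a in assignments))
    rows = []
    lo, hi = BALKWILL_NORM_RANGE_DEG
    for c in clusters:
        sub = derived.loc[assignments == c]
        n, ie_m, ie_sd = _mean_sd(sub["ie_ax_mm"].to_numpy())
        _, bk_m, bk_sd = _mean_sd(sub["balkwill_deg"].to_numpy())
        flag = "within" if lo <= bk_m <= hi else ("below" if bk_m < lo else "above")
        rows.append(
            {
                "cluster": c,
                "phenotype": (labels or {}).get(c, ""),
                "n": n,
                "ie_ax_mean": ie_m,
                "ie_ax_sd": ie_sd,
                "ie_ax_norm_mm": BONWILL_NORM_MM,
                "ie_ax_dev_from_norm": ie_m - BONWILL_NORM_MM,
                "balkwill_mean": bk_m,
                "balkwill_sd": bk_sd,
                "balkwill_norm_lo": lo,
                "balkwill_norm_hi": hi,
                "balkwill_flag": flag,
            }
        )
    return pd.DataFrame(rows)
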