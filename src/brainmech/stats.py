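"""Group-comparison statistics for cohort summary metrics.

Fixed-effects two-way ANOVA (age group x sex, Type II sums of squares for
the unbalanced cohorts) and one-way ANOVA with Tukey HSD post-hoc pairwise
comparisons run conditionally on overall significance.

The Type II decomposition is computed by nested least-squares model
comparison on dummy-coded design matrices: each main effect's sum of
squares is the residual-SS drop from adding that factor to the model
containing the other main effect; the interaction SS is the drop from the
additive model to the full model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "two_way_anova",
    "one_way_anova_posthoc",
    "metric_table",
]


def metric_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Build a subject-metric table (subject_id, age_group, sex, metric_name, value)."""
    df = pd.DataFrame(rows)
    required = {"subject_id", "age_group", "sex", "metric_name", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["subject_id", "metric_name"])
    if dup.any():
        raise ValueError("more than one value per subject per metric")
    return df


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded dummy columns (reference level dropped)."""
    out = np.zeros((len(codes), n_levels - 1))
    for j in range(1, n_levels):
        out[codes == j, j - 1] = 1.0
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(table: pd.DataFrame, metric: str) -> dict:
    """Two-way fixed-effects ANOVA with interaction, Type II sums of squares.

    ``table`` follows the subject-metric schema (see :func:`metric_table`).
    Returns ``F_age, p_age, F_sex, p_sex, F_interaction, p_interaction``
    plus the residual df; a zero residual variance is flagged
    ``degenerate`` with infinite F.
    """
    df = table[table["metric_name"] == metric]
    if df.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    y = df["value"].to_numpy(dtype=float)
    a_codes, a_levels = pd.factorize(df["age_group"], sort=True)
    b_codes, b_levels = pd.factorize(df["sex"], sort=True)
    na, nb = len(a_levels), len(b_levels)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 levels per factor")
    cells = pd.crosstab(a_codes, b_codes)
    if cells.shape != (na, nb) or (cells.to_numpy() == 0).any():
        raise ValueError("empty design cell: interaction not estimable")

    n = len(y)
    one = np.ones((n, 1))
    A = _dummies(a_codes, na)
    B = _dummies(b_codes, nb)
    AB = np.einsum("ij,ik->ijk", A, B).reshape(n, -1)
    X_full = np.hstack([one, A, B, AB])
    rss_full = _rss(X_full, y)
    rss_ab = _rss(np.hstack([one, A, B]), y)
    rss_a = _rss(np.hstack([one, A]), y)
    rss_b = _rss(np.hstack([one, B]), y)

    df_a, df_b = na - 1, nb - 1
    df_int = df_a * df_b
    df_res = n - na * nb
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")
    ss_a = rss_b - rss_ab       # Type II: A adjusted for B
    ss_b = rss_a - rss_ab
    ss_int = rss_ab - rss_full
    mse = rss_full / df_res
    result = {"df_residual": df_res, "degenerate": False}
    if mse <= 1e-30 * max(1.0, float(y @ y)):
        result["degenerate"] = True
        for name in ("age", "sex", "interaction"):
            result[f"F_{name}"] = np.inf
            result[f"p_{name}"] = 0.0
        return result
    for name, ss, d in (("age", ss_a, df_a), ("sex", ss_b, df_b), ("interaction", ss_int, df_int)):
        F = max(ss, 0.0) / d / mse
        result[f"F_{name}"] = float(F)
        result[f"p_{name}"] = float(sps.f.sf(F, d, df_res))
    return result


def one_way_anova_posthoc(table: pd.DataFrame, metric: str, alpha: float = 0.05) -> dict:
    """One-way ANOVA by age group with conditional Tukey HSD post-hoc.

    The pairwise comparisons run only when the overall F-test is significant
    at ``alpha``, mirroring the conditional procedure used for cohort
    deformation metrics.  Returns ``{"F", "p", "pairwise": [(groupA, groupB,
    p_adj, significant), ...]}`` (``pairwise`` empty when not significant).
    """
    df = table[table["metric_name"] == metric]
    if df.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    groups = sorted(df["age_group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [df.loc[df["age_group"] == g, "value"].to_numpy(dtype=float) for g in groups]
    for g, s in zip(groups, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    F, p = sps.f_oneway(*samples)
    out = {"F": float(F), "p": float(p), "groups": groups, "pairwise": []}
    if p < alpha:
        hsd = sps.tukey_hsd(*samples)
        for i, j in combinations(range(len(groups)), 2):
            p_adj = float(hsd.pvalue[i, j])
            out["pairwise"].append((groups[i], groups[j], p_adj, p_adj < alpha))
    return out
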