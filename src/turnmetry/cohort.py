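"""Cross-sectional cohort comparison of turning parameters.

Turns within a subject are correlated, so the unit of analysis is the
subject: each subject's turns are averaged first (unweighted), and the
group comparison runs on the per-subject means. The comparison itself is a
two-tailed independent-samples t-test (pooled-variance Student's t by
default, df = n_a + n_b - 2; Welch available), a 95% CI on the mean
difference, and Cohen's d with pooled SD,

    d = (mean_a - mean_b) / s_p,
    s_p = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)),

which for equal n reduces to sqrt((s_a^2 + s_b^2) / 2). All of these are
also computable from printed summary statistics (means, SDs, n), so a
published table can be checked without the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "per_subject_means",
    "two_sample_t",
    "cohens_d",
    "cohens_d_from_stats",
    "compare_groups",
    "compare_groups_from_summary",
]


class DegenerateDataError(ValueError):
    """Zero variance (or otherwise degenerate) input for a variance-based test."""


@dataclass
class GroupComparison:
    """Result of one group-difference analysis on a single measure."""

    measure: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float
    p_two_tailed: float
    mean_diff: float
    ci95: tuple[float, float]
    cohens_d: float
    variant: str = "pooled"

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "group_a": {"mean": self.mean_a, "sd": self.sd_a, "n": self.n_a},
            "group_b": {"mean": self.mean_b, "sd": self.sd_b, "n": self.n_b},
            "t_stat": self.t_stat,
            "p_two_tailed": self.p_two_tailed,
            "mean_diff": self.mean_diff,
            "ci95": list(self.ci95),
            "cohens_d": self.cohens_d,
            "variant": self.variant,
        }


def per_subject_means(turns: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-turn estimates to one row per subject.

    Parameters
    ----------
    turns : DataFrame
        Columns ``subject_id``, ``group``, ``theta_deg`` and (optionally)
        ``wmax_deg_s``; one row per turn.

    Returns
    -------
    DataFrame with columns ``subject_id``, ``group``, ``mean_theta`` and
    (when available) ``mean_wmax``; subject means are unweighted over that
    subject's turns. Subjects with zero turns are simply absent.
    """
    required = {"subject_id", "group", "theta_deg"}
    missing = required - set(turns.columns)
    if missing:
        raise ValueError(f"turn table lacks column(s): {sorted(missing)}")
    agg = {"theta_deg": "mean"}
    if "wmax_deg_s" in turns.columns:
        agg["wmax_deg_s"] = "mean"
    out = (
        turns.groupby(["subject_id", "group"], as_index=False)
        .agg(agg)
        .rename(columns={"theta_deg": "mean_theta", "wmax_deg_s": "mean_wmax"})
    )
    # a subject must not sit in two groups
    dup = out["subject_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"subject(s) in multiple groups: {out.loc[dup, 'subject_id'].tolist()}"
        )
    return out


def _describe(values: Sequence[float]) -> tuple[float, float, int]:
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values in group")
    return float(v.mean()), float(v.std(ddof=1)), int(v.size)


def two_sample_t(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: str = "pooled",
) -> tuple[float, float, tuple[float, float]]:
    """Two-tailed independent-samples t-test with a 95% CI on mean_a - mean_b.

    Returns ``(t_stat, p_two_tailed, (ci_low, ci_high))``. The pooled
    variant assumes equal variances (df = n_a + n_b - 2); ``welch`` drops
    that assumption.
    """
    ma, sa, na = _describe(values_a)
    mb, sb, nb = _describe(values_b)
    return _t_from_stats(ma, sa, na, mb, sb, nb, variant)


def _t_from_stats(ma, sa, na, mb, sb, nb, variant):
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if sa == 0 and sb == 0:
        raise DegenerateDataError("zero variance in both groups")
    res = stats.ttest_ind_from_stats(
        ma, sa, na, mb, sb, nb, equal_var=(variant == "pooled")
    )
    diff = ma - mb
    if variant == "pooled":
        df = na + nb - 2
        sp2 = ((na - 1) * sa**2 + (nb - 1) * sb**2) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
    else:
        se = np.sqrt(sa**2 / na + sb**2 / nb)
        df = se**4 / (
            (sa**2 / na) ** 2 / (na - 1) + (sb**2 / nb) ** 2 / (nb - 1)
        )
    tcrit = stats.t.ppf(0.975, df)
    ci = (diff - tcrit * se, diff + tcrit * se)
    return float(res.statistic), float(res.pvalue), (float(ci[0]), float(ci[1]))


def cohens_d(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Standardised mean difference with pooled SD (sample SDs, ddof=1)."""
    ma, sa, na = _describe(values_a)
    mb, sb, nb = _describe(values_b)
    return cohens_d_from_stats(ma, sa, na, mb, sb, nb)


def cohens_d_from_stats(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """Cohen's d from summary statistics."""
    df = n_a + n_b - 2
    if df <= 0:
        raise ValueError("need at least 2 values per group")
    sp = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df)
    if sp == 0:
        raise DegenerateDataError("zero pooled SD")
    return float((mean_a - mean_b) / sp)


def compare_groups(
    subject_table: pd.DataFrame,
    measure: str = "theta",
    group_a: str = "PD",
    group_b: str = "control",
    variant: str = "pooled",
) -> GroupComparison:
    """Full group comparison on per-subject means.

    ``measure`` is ``"theta"`` (mean turning angle) or ``"wmax"`` (mean
    maximum angular velocity); the corresponding column of the
    :func:`per_subject_means` table is used. The difference, CI and d are
    oriented as group_a minus group_b.
    """
    col = {"theta": "mean_theta", "wmax": "mean_wmax"}.get(measure)
    if col is None:
        raise ValueError("measure must be 'theta' or 'wmax'")
    if col not in subject_table.columns:
        raise ValueError(f"subject table has no column {col!r}")
    groups = set(subject_table["group"])
    if not {group_a, group_b} <= groups:
        raise ValueError(
            f"need both groups {group_a!r} and {group_b!r}; table has {sorted(groups)}"
        )
    va = subject_table.loc[subject_table["group"] == group_a, col].to_numpy()
    vb = subject_table.loc[subject_table["group"] == group_b, col].to_numpy()
    ma, sa, na = _describe(va)
    mb, sb, nb = _describe(vb)
    return compare_groups_from_summary(
        ma, sa, na, mb, sb, nb, measure=measure, variant=variant
    )


def compare_groups_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    measure: str = "theta",
    variant: str = "pooled",
) -> GroupComparison:
    """Group comparison from printed summary statistics (no raw data needed)."""
    t_stat, p, ci = _t_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b, variant)
    return GroupComparison(
        measure=measure,
        mean_a=mean_a,
        sd_a=sd_a,
        n_a=n_a,
        mean_b=mean_b,
        sd_b=sd_b,
        n_b=n_b,
        t_stat=t_stat,
        p_two_tailed=p,
        mean_diff=mean_a - mean_b,
        ci95=ci,
        cohens_d=cohens_d_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b),
        variant=variant,
    )
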