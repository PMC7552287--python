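"""Descriptive group summaries and nonparametric comparison for endpoint tables.

Experiments produce one metric per animal per condition (temperature step,
pesticide dose). This module provides the descriptive layer — mean +/- SEM
per group, normalization relative to a control group — and a two-sided
Mann-Whitney U comparison. It is deliberately thin: significance machinery
beyond the rank-sum test is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupSummary", "summarize", "summarize_table", "compare_groups", "relative_to_control"]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float  # sample SD / sqrt(n); NaN for n = 1


def summarize(values: np.ndarray, group: str = "") -> GroupSummary:
    """Mean +/- SEM of one group; SEM uses the n-1 sample SD.

    A single-value group has an undefined SEM, reported as NaN rather than
    zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError(f"empty group {group!r}")
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
    return GroupSummary(group=group, n=int(v.size), mean=float(v.mean()), sem=sem)


def summarize_table(df: pd.DataFrame, group_col: str, value_col: str) -> pd.DataFrame:
    """Per-group mean/SEM/n table from a long-format metrics DataFrame."""
    rows = [
        summarize(sub[value_col].to_numpy(), group=str(g))
        for g, sub in df.groupby(group_col, sort=False)
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def compare_groups(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U statistic of group a, p).

    The exact null distribution is used for groups of up to 8 without ties;
    larger or tied samples use the normal approximation with tie correction
    (no continuity correction, so the approximation is symmetric in U).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"each group needs >= 3 values, got {len(a)} and {len(b)}")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if max(len(a), len(b)) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def relative_to_control(
    df: pd.DataFrame, group_col: str, value_col: str, control: str
) -> pd.DataFrame:
    """Normalize values by the control-group mean (control maps to 1 exactly).

    Adds a ``relative`` column = value / mean(control values).
    """
    ctrl = df.loc[df[group_col].astype(str) == str(control), value_col]
    if ctrl.empty:
        raise ValueError(f"control group {control!r} not found in {group_col!r}")
    out = df.copy()
    out["relative"] = out[value_col] / ctrl.mean()
    return out
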