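"""Two-stage aggregation and between-condition comparisons.

The unit of analysis is the coverslip: per-bouton measurements are averaged
within each coverslip, and condition means +/- SEM are computed over the
coverslip means (unweighted, regardless of bouton counts).  Conditions are
compared with a two-tailed unpaired Student's t-test (equal variance, the
historical default of the stated analysis software); Welch's correction is
available behind a flag.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


class StatsError(ValueError):
    pass


@dataclass
class Comparison:
    metric: str
    condition_a: str
    condition_b: str
    t: float
    p: float
    df: float
    significant: bool


def coverslip_means(
    df: pd.DataFrame,
    metric: str,
    coverslip_col: str = "coverslip_id",
) -> np.ndarray:
    """Per-coverslip means of one metric, dropping absent values."""
    sub = df[[coverslip_col, metric]].dropna()
    if sub.empty:
        raise StatsError(f"no values for metric {metric!r}")
    return sub.groupby(coverslip_col)[metric].mean().to_numpy()


def summarize(
    df: pd.DataFrame,
    metrics: Optional[Sequence[str]] = None,
    condition_col: str = "genotype",
    coverslip_col: str = "coverslip_id",
) -> pd.DataFrame:
    """Condition mean +/- SEM over coverslip means, one row per
    (condition, metric).

    SEM is sd/sqrt(n) over coverslip means; with a single coverslip the mean
    is reported and SEM is absent (with a warning).
    """
    if metrics is None:
        skip = {condition_col, coverslip_col, "bouton_id"}
        metrics = [
            c for c in df.columns if c not in skip and pd.api.types.is_numeric_dtype(df[c])
        ]
    rows = []
    for cond, grp in df.groupby(condition_col, sort=True):
        for metric in metrics:
            sub = grp[[coverslip_col, metric]].dropna()
            if sub.empty:
                continue
            cs = sub.groupby(coverslip_col)[metric].mean()
            n = len(cs)
            mean = float(cs.mean())
            if n >= 2:
                sem = float(cs.std(ddof=1) / np.sqrt(n))
            else:
                warnings.warn(
                    f"{cond}/{metric}: single coverslip, SEM not defined", stacklevel=2
                )
                sem = float("nan")
            rows.append(
                {
                    "condition": cond,
                    "metric": metric,
                    "n_coverslips": n,
                    "mean": mean,
                    "sem": sem,
                }
            )
    return pd.DataFrame(rows)


def compare(
    a: Sequence[float],
    b: Sequence[float],
    metric: str = "",
    condition_a: str = "A",
    condition_b: str = "B",
    welch: bool = False,
) -> Comparison:
    """Two-tailed unpaired t-test on two sets of coverslip means."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("need >= 2 coverslip means per group")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0 and var_b == 0:
        if a.mean() == b.mean():
            df = len(a) + len(b) - 2
            return Comparison(metric, condition_a, condition_b, 0.0, 1.0, df, False)
        raise StatsError("degenerate: zero variance in both groups, unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = (var_a / len(a) + var_b / len(b)) ** 2 / (
            (var_a / len(a)) ** 2 / (len(a) - 1) + (var_b / len(b)) ** 2 / (len(b) - 1)
        )
    else:
        df = len(a) + len(b) - 2
    return Comparison(
        metric, condition_a, condition_b, float(t), float(p), float(df), bool(p < ALPHA)
    )


def pairwise_compare(
    df: pd.DataFrame,
    metrics: Optional[Sequence[str]] = None,
    condition_col: str = "genotype",
    coverslip_col: str = "coverslip_id",
    welch: bool = False,
) -> pd.DataFrame:
    """All pairwise condition comparisons for each metric with >= 2
    coverslips in both groups."""
    if metrics is None:
        skip = {condition_col, coverslip_col, "bouton_id"}
        metrics = [
            c for c in df.columns if c not in skip and pd.api.types.is_numeric_dtype(df[c])
        ]
    conditions = sorted(df[condition_col].dropna().unique())
    rows = []
    for i, ca in enumerate(conditions):
        for cb in conditions[i + 1 :]:
            for metric in metrics:
                try:
                    ma = coverslip_means(df[df[condition_col] == ca], metric, coverslip_col)
                    mb = coverslip_means(df[df[condition_col] == cb], metric, coverslip_col)
                    cmp_ = compare(ma, mb, metric, ca, cb, welch=welch)
                except StatsError:
                    continue
                rows.append(vars(cmp_))
    return pd.DataFrame(rows)
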