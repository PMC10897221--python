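"""Summary statistics for per-cell measurements: mean ± SEM tables and
unpaired two-tailed t tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["summarize", "unpaired_ttest", "pairwise_ttests"]


def summarize(
    df: pd.DataFrame,
    value: str,
    by: list[str] | str,
) -> pd.DataFrame:
    """Group ``df[value]`` by the ``by`` columns and report mean, SEM and n.

    SEM is the sample standard deviation (ddof=1) over sqrt(n); groups with
    n < 2 raise, since their SEM is undefined. n counts the rows actually
    contributing, i.e. after any upstream exclusion of degenerate cells.
    """
    if isinstance(by, str):
        by = [by]
    rows = []
    for key, grp in df.groupby(by, sort=True, dropna=False):
        vals = grp[value].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(
                f"group {key!r} has n={vals.size} < 2; SEM undefined"
            )
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(
                zip(by, key),
                mean=float(vals.mean()),
                sem=float(vals.std(ddof=1) / np.sqrt(vals.size)),
                n=int(vals.size),
            )
        )
    return pd.DataFrame(rows)


def unpaired_ttest(
    group_a, group_b, *, equal_var: bool = False
) -> tuple[float, float]:
    """Unpaired two-tailed t test; Welch by default, pooled on request.

    Returns ``(t, p)``. Two groups that are both constant with equal means
    get the ``t=0, p=1`` convention; a zero-variance comparison with unequal
    means is an error rather than an infinite statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def pairwise_ttests(
    df: pd.DataFrame,
    value: str,
    by: str,
    *,
    equal_var: bool = False,
) -> pd.DataFrame:
    """All pairwise unpaired t tests between the levels of ``df[by]``."""
    levels = sorted(df[by].dropna().unique().tolist(), key=str)
    rows = []
    for i, ga in enumerate(levels):
        for gb in levels[i + 1 :]:
            t, p = unpaired_ttest(
                df.loc[df[by] == ga, value],
                df.loc[df[by] == gb, value],
                equal_var=equal_var,
            )
            rows.append({"group_a": ga, "group_b": gb, "t": t, "p": p})
    return pd.DataFrame(rows)
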