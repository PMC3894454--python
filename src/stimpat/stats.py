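"""Split-apply-combine statistics for long-format behavioural tables.

`aggregate` groups a long-format table by plotting factors (subplots, rows,
cols) and one error-bar unit (typically the participant), applying a reducer
(mean by default) to each cell.  `error_bars` turns the per-unit columns
into mean +- SEM, and `significance_stars` runs the one- or two-sample
t-test behind star annotations (* p < 0.05, ** p < 0.01).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["aggregate", "error_bars", "significance_stars"]


def aggregate(table: pd.DataFrame,
              values: str,
              yerr: str,
              rows: str | None = None,
              cols: str | None = None,
              subplots: str | None = None,
              func="mean") -> pd.DataFrame:
    """Group a long table by (subplots, rows, cols, yerr) and reduce `values`.

    Returns a DataFrame whose index is the factor combinations (subplots,
    rows, cols — whichever were given) and whose columns are the `yerr`
    units, each cell holding ``func`` applied to exactly the records that
    match the combination.  Empty combinations stay missing (NaN), never
    zero.

    Parameters
    ----------
    func
        Reducer applied per group: a callable, or a name pandas understands
        (``"mean"``, ``"median"``, ``"count"``, ``"sum"``...).
    """
    factors = [f for f in (subplots, rows, cols) if f is not None]
    for col in factors + [yerr, values]:
        if col not in table.columns:
            raise KeyError(f"column {col!r} not found in table")
    if not factors:
        raise ValueError("at least one of subplots/rows/cols is required")
    grouped = table.groupby(factors + [yerr], sort=True, observed=True)[values]
    reduced = grouped.agg(func)
    return reduced.unstack(yerr)


def error_bars(agg: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM across the error-bar unit columns of an aggregated table.

    SEM uses the sample standard deviation (n-1 denominator) divided by
    sqrt(n), with n the number of non-missing units in the cell.  Cells with
    a single unit get a missing SEM rather than zero.
    """
    n = agg.notna().sum(axis=1)
    mean = agg.mean(axis=1)
    sem = agg.std(axis=1, ddof=1) / np.sqrt(n)
    sem[n < 2] = np.nan
    return pd.DataFrame({"mean": mean, "sem": sem})


def significance_stars(sample_a,
                       sample_b=None,
                       kind: str = "one_sample",
                       paired: bool | None = None,
                       three_levels: bool = False):
    """t-test with the star annotation convention.

    ``kind="one_sample"`` tests `sample_a` against the scalar reference
    `sample_b` (default 0).  ``kind="two_sample"`` compares two samples;
    when `paired` is None it defaults to a paired test if both inputs are
    pandas Series with identical indexes (matching error-bar units),
    otherwise an independent pooled-variance test.

    Returns ``(t, p, stars)`` where stars is ``"**"`` if p < 0.01, ``"*"``
    if p < 0.05, else ``""`` (with ``three_levels=True``, ``"***"`` for
    p < 0.001).
    """
    a = np.asarray(sample_a, dtype=float)
    if kind == "one_sample":
        ref = 0.0 if sample_b is None else float(np.asarray(sample_b))
        if len(a) < 2:
            raise ValueError("one-sample test needs n >= 2")
        if np.ptp(a) == 0:
            raise ValueError("degenerate test: sample has zero variance")
        t, p = sps.ttest_1samp(a, popmean=ref)
    elif kind == "two_sample":
        if sample_b is None:
            raise ValueError("two-sample test needs a second sample")
        b = np.asarray(sample_b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("two-sample test needs n >= 2 in both samples")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ValueError("degenerate test: both samples have zero variance")
        if paired is None:
            paired = (isinstance(sample_a, pd.Series)
                      and isinstance(sample_b, pd.Series)
                      and sample_a.index.equals(sample_b.index))
        if paired:
            t, p = sps.ttest_rel(a, b)
        else:
            t, p = sps.ttest_ind(a, b, equal_var=True)
    else:
        raise ValueError("kind must be 'one_sample' or 'two_sample'")

    t, p = float(t), float(p)
    if three_levels and p < 0.001:
        stars = "***"
    elif p < 0.01:
        stars = "**"
    elif p < 0.05:
        stars = "*"
    else:
        stars = ""
    return t, p, stars
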