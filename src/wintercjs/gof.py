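"""Contingency-table goodness-of-fit components for the CJS model.

These are the classical U-CARE-style diagnostics computed from the
new/old-stratified m-array:

* TEST3.SR — transience: do newly marked and previously marked individuals
  released at the same occasion differ in whether they are ever seen again?
* TEST3.SM — among individuals seen again, do new and old releases differ in
  *when* they are first seen again?
* TEST2.CT — trap-dependence: among individuals alive and reencountered
  after occasion i, does being detected at i change the odds of an immediate
  (i+1) versus later reencounter?
* TEST2.CL — the timing complement of TEST2.CT for reencounters beyond i+1.

All components are Pearson chi-squares summed over groups and occasions.
Tables with a zero margin contribute nothing; R x C tables pool adjacent
columns whose expected count falls below 2.  Sparse tables where the
chi-square approximation is unreliable are treated as degenerate
(Cochran-style validity rule: every expected count must reach 3 in the 2x2
components and 2 after pooling in the R x C components).  The
overdispersion coefficient c-hat is a ratio of summed statistics to summed
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .encounter import MArray

__all__ = [
    "Chi2Result",
    "test3_sr",
    "test3_sm",
    "test2_ct",
    "test2_cl",
    "test3_sr_signed",
    "chat",
    "gof_report",
]

_POOL_THRESHOLD = 2.0
_MIN_EXPECTED_2X2 = 3.0


@dataclass
class Chi2Result:
    name: str
    statistic: float
    df: int
    components: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def p_value(self) -> float:
        if self.df == 0:
            return 1.0
        return float(stats.chi2.sf(self.statistic, self.df))


def _pearson(
    table: np.ndarray, min_expected: float = _POOL_THRESHOLD
) -> tuple[float, int] | None:
    """Pearson chi-square for a 2-row table; None if degenerate.

    A table is degenerate when a margin is zero or when any expected count
    falls below ``min_expected`` (the chi-square approximation is unreliable
    there and such tables cannot be pooled further).
    """
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    N = table.sum()
    if N <= 0 or np.any(rows <= 0) or np.any(cols <= 0):
        return None
    E = np.outer(rows, cols) / N
    if (E < min_expected).any():
        return None
    stat = float(((table - E) ** 2 / E).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, df


def _pool_columns(table: np.ndarray) -> np.ndarray:
    """Drop all-zero columns, then merge adjacent columns with expected < 2.

    The rightmost offending column is folded into its left neighbour until no
    expected cell is below the threshold or only two columns remain.
    """
    table = np.asarray(table, dtype=float)
    table = table[:, table.sum(axis=0) > 0]
    while table.shape[1] > 2:
        rows = table.sum(axis=1)
        cols = table.sum(axis=0)
        N = table.sum()
        if N <= 0:
            break
        E = np.outer(rows, cols) / N
        bad = np.flatnonzero((E < _POOL_THRESHOLD).any(axis=0))
        if bad.size == 0:
            break
        j = int(bad[-1])
        if j == 0:
            j = 1
        table[:, j - 1] += table[:, j]
        table = np.delete(table, j, axis=1)
    return table


def _collect(name: str, rows: list[tuple]) -> Chi2Result:
    comp = pd.DataFrame(
        rows, columns=["component", "group", "occasion", "statistic", "df"]
    )
    stat = float(comp["statistic"].sum()) if len(comp) else 0.0
    df = int(comp["df"].sum()) if len(comp) else 0
    return Chi2Result(name, stat, df, comp)


def test3_sr(marray: MArray) -> Chi2Result:
    """Transience component: ever reencountered, new vs old releases."""
    T = len(marray.occasions)
    rows = []
    never = marray.never
    seen = marray.m.sum(axis=-1)
    for g, gname in enumerate(marray.groups):
        for i in range(T - 1):
            table = np.array([
                [seen[g, 0, i], never[g, 0, i]],
                [seen[g, 1, i], never[g, 1, i]],
            ])
            res = _pearson(table, _MIN_EXPECTED_2X2)
            if res is None:
                continue
            rows.append(("3.SR", gname, marray.occasions[i], res[0], res[1]))
    return _collect("TEST3.SR", rows)


def test3_sm(marray: MArray) -> Chi2Result:
    """Timing of first reencounter, new vs old releases (reencountered only)."""
    T = len(marray.occasions)
    rows = []
    for g, gname in enumerate(marray.groups):
        for i in range(T - 1):
            table = np.stack([
                marray.m[g, 0, i, i + 1 :],
                marray.m[g, 1, i, i + 1 :],
            ]).astype(float)
            table = _pool_columns(table)
            if table.shape[1] < 2:
                continue
            res = _pearson(table)
            if res is None:
                continue
            rows.append(("3.SM", gname, marray.occasions[i], res[0], res[1]))
    return _collect("TEST3.SM", rows)


def _ct_cl_rows(marray: MArray, g: int, i: int) -> tuple[np.ndarray, np.ndarray]:
    """Next-reencounter count vectors after occasion i for individuals seen
    at i (releases at i) vs known-alive-but-not-seen at i (released earlier,
    first reencountered after i)."""
    T = len(marray.occasions)
    seen_at_i = marray.m[g, :, i, i + 1 :].sum(axis=0).astype(float)
    not_seen = marray.m[g, :, :i, i + 1 :].sum(axis=(0, 1)).astype(float)
    return seen_at_i, not_seen


def test2_ct(marray: MArray) -> Chi2Result:
    """Trap-dependence: immediate (i+1) vs later reencounter, by detection
    status at occasion i."""
    T = len(marray.occasions)
    rows = []
    for g, gname in enumerate(marray.groups):
        for i in range(1, T - 1):
            a, b = _ct_cl_rows(marray, g, i)
            table = np.array([
                [a[0], a[1:].sum()],
                [b[0], b[1:].sum()],
            ])
            res = _pearson(table, _MIN_EXPECTED_2X2)
            if res is None:
                continue
            rows.append(("2.CT", gname, marray.occasions[i], res[0], res[1]))
    return _collect("TEST2.CT", rows)


def test2_cl(marray: MArray) -> Chi2Result:
    """Timing of non-immediate reencounters, by detection status at i."""
    T = len(marray.occasions)
    rows = []
    for g, gname in enumerate(marray.groups):
        for i in range(1, T - 2):
            a, b = _ct_cl_rows(marray, g, i)
            table = np.stack([a[1:], b[1:]])
            table = _pool_columns(table)
            if table.shape[1] < 2:
                continue
            res = _pearson(table)
            if res is None:
                continue
            rows.append(("2.CL", gname, marray.occasions[i], res[0], res[1]))
    return _collect("TEST2.CL", rows)


def test3_sr_signed(marray: MArray) -> float:
    """Directional transience statistic (supplementary, not used for c-hat).

    Positive values indicate an excess of newly marked individuals that are
    never reencountered, the signature of transients.  Combines the
    per-table (observed - expected) of the new/never cell over a
    hypergeometric variance.
    """
    T = len(marray.occasions)
    never = marray.never
    seen = marray.m.sum(axis=-1)
    num = 0.0
    var = 0.0
    for g in range(len(marray.groups)):
        for i in range(T - 1):
            table = np.array([
                [seen[g, 0, i], never[g, 0, i]],
                [seen[g, 1, i], never[g, 1, i]],
            ], dtype=float)
            rows_ = table.sum(axis=1)
            cols_ = table.sum(axis=0)
            N = table.sum()
            if N <= 1 or np.any(rows_ <= 0) or np.any(cols_ <= 0):
                continue
            E = rows_[0] * cols_[1] / N
            V = rows_[0] * rows_[1] * cols_[0] * cols_[1] / (N**2 * (N - 1))
            num += table[0, 1] - E
            var += V
    return float(num / np.sqrt(var)) if var > 0 else 0.0


def chat(
    components: list[Chi2Result],
    include: tuple[str, ...] = ("TEST2.CT", "TEST2.CL", "TEST3.SM"),
    floor: bool = True,
) -> tuple[float, dict]:
    """Overdispersion coefficient c-hat = sum(chi2) / sum(df).

    The conventional usage here excludes TEST3.SR, whose signal is absorbed
    by estimating separate first-interval and later survival, and pools the
    remaining components.  Values below 1 are floored at 1 for ranking; the
    note dict records the raw ratio.
    """
    chosen = [c for c in components if c.name in include]
    total_stat = sum(c.statistic for c in chosen)
    total_df = sum(c.df for c in chosen)
    if total_df <= 0:
        raise ValueError("zero total degrees of freedom for c-hat")
    raw = total_stat / total_df
    value = max(1.0, raw) if floor else raw
    note = {
        "statistic": total_stat,
        "df": total_df,
        "raw": raw,
        "floored": floor and raw < 1.0,
        "components": [c.name for c in chosen],
    }
    return value, note


def gof_report(marray: MArray) -> pd.DataFrame:
    """Per-component summary table (name, statistic, df, p)."""
    comps = [test3_sr(marray), test3_sm(marray), test2_ct(marray), test2_cl(marray)]
    return pd.DataFrame(
        [(c.name, c.statistic, c.df, c.p_value) for c in comps],
        columns=["component", "statistic", "df", "p_value"],
    )
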