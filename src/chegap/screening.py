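"""Contingency tables and Pearson chi-square screening of covariates.

Each candidate explanatory variable is cross-classified against the CHE
flag; variables significantly associated (Pearson chi-square without
continuity correction, p < alpha) enter the decomposition.  Rows carrying
the missing sentinel on either variable are excluded from that table, with
the excluded count reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survey import MISSING

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "ScreeningReport",
    "tabulate",
    "chi_square",
    "screen_variables",
]


class DegenerateTableError(ValueError):
    """A variable is constant (single observed level); no table exists."""


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-classification counts of two categorical variables."""

    row_variable: str
    column_variable: str
    row_levels: tuple[str, ...]
    column_levels: tuple[str, ...]
    counts: np.ndarray
    n_excluded_missing: int = 0

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(
            row_variable=self.column_variable,
            column_variable=self.row_variable,
            row_levels=self.column_levels,
            column_levels=self.row_levels,
            counts=self.counts.T.copy(),
            n_excluded_missing=self.n_excluded_missing,
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected_min: float
    warning_small_cells: bool


def tabulate(
    frame: pd.DataFrame,
    row_variable: str,
    column_variable: str,
    row_levels: tuple[str, ...] | None = None,
    column_levels: tuple[str, ...] | None = None,
) -> ContingencyTable:
    """Cross-classify two categorical columns of an analysis frame.

    Rows holding the missing sentinel on either variable are excluded and
    counted.  Levels default to those observed; declared level lists may be
    passed to force the table shape (unobserved levels count zero).  A
    variable with a single level is degenerate.
    """
    sub = frame[[row_variable, column_variable]].astype(str)
    keep = (sub[row_variable] != MISSING) & (sub[column_variable] != MISSING)
    excluded = int((~keep).sum())
    sub = sub[keep]
    ct = pd.crosstab(sub[row_variable], sub[column_variable])
    if row_levels is not None:
        ct = ct.reindex(index=list(row_levels), fill_value=0)
    if column_levels is not None:
        ct = ct.reindex(columns=list(column_levels), fill_value=0)
    if ct.shape[0] < 2:
        raise DegenerateTableError(
            f"{row_variable!r} has a single observed level: {list(ct.index)}"
        )
    if ct.shape[1] < 2:
        raise DegenerateTableError(
            f"{column_variable!r} has a single observed level: {list(ct.columns)}"
        )
    return ContingencyTable(
        row_variable=row_variable,
        column_variable=column_variable,
        row_levels=tuple(ct.index),
        column_levels=tuple(ct.columns),
        counts=ct.to_numpy(dtype=np.int64),
        n_excluded_missing=excluded,
    )


def chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    counts = table.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        empty_rows = [l for l, s in zip(table.row_levels, row_sums) if s == 0]
        empty_cols = [l for l, s in zip(table.column_levels, col_sums) if s == 0]
        raise ValueError(f"zero margin for level(s): {empty_rows + empty_cols}")
    stat, p, df, expected = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        expected_min=float(expected.min()),
        warning_small_cells=bool(expected.min() < 5),
    )


@dataclass
class ScreeningReport:
    """Per-variable chi-square results and the selected subset."""

    outcome: str
    alpha: float
    results: dict[str, ChiSquareResult] = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variable": v,
                "statistic": r.statistic,
                "df": r.df,
                "p_value": r.p_value,
                "selected": v in self.selected,
            }
            for v, r in self.results.items()
        ]
        return pd.DataFrame(rows)


def screen_variables(
    frame: pd.DataFrame,
    candidates: list[str],
    outcome: str = "che",
    alpha: float = 0.05,
) -> ScreeningReport:
    """Select covariates associated with the outcome at p < alpha.

    Selection preserves candidate order; the full per-variable report is
    retained for audit regardless of selection.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    report = ScreeningReport(outcome=outcome, alpha=alpha)
    for var in candidates:
        result = chi_square(tabulate(frame, var, outcome))
        report.results[var] = result
        if result.p_value < alpha:
            report.selected.append(var)
    return report
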