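"""Per-child z-score tables: I/O, composite reading scores, predictor screening.

The single tabular currency of the pipeline is the :class:`CohortTable` — one row
per child, one column per z-scored measure, ``NaN`` for an explicitly missing
measurement.  All measures are assumed oriented so that a higher z-score means
better performance (speed measures included); orientation is the data preparer's
contract and is not second-guessed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "CompositeSpec",
    "ScreeningReport",
    "read_cohort",
    "write_cohort",
    "composite_score",
    "screen_predictors",
]

#: minimum number of pairwise-complete observations for a correlation to be evaluable
MIN_PAIRWISE_N = 3


@dataclass
class CohortTable:
    """A cohort of children with z-scored measures.

    Parameters
    ----------
    data
        DataFrame indexed by child identifier (unique), with float columns;
        ``NaN`` marks an explicitly missing measurement.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate child_id values: {dupes}")
        # coerce to float so that "missing" is always an explicit NaN
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric measure column: {exc}") from exc

    @property
    def n_children(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"unknown measure column {name!r}")
        return self.data[name]

    def complete_cases(self, columns: Sequence[str] | None = None) -> "CohortTable":
        """Children with no missing value in *columns* (default: all columns)."""
        cols = list(columns) if columns is not None else self.columns
        return CohortTable(self.data.dropna(subset=cols).copy())

    def equals(self, other: "CohortTable") -> bool:
        return self.data.equals(other.data)


@dataclass(frozen=True)
class CompositeSpec:
    """A named composite measure: the arithmetic mean of component z-scores."""

    name: str
    components: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("composite needs at least one component")
        object.__setattr__(self, "components", tuple(self.components))


@dataclass(frozen=True)
class ScreeningReport:
    """Outcome of screening one candidate predictor against both reading outcomes."""

    candidate: str
    r_accuracy: float
    r_speed: float
    selected: bool
    reason: str


def read_cohort(
    path: str | Path,
    missing_token: str = "NA",
    id_col: str = "child_id",
) -> CohortTable:
    """Read a comma-separated cohort table.

    Cells equal to *missing_token* become missing; any other non-numeric cell is a
    hard error naming its row and column.  Row numbers in error messages count the
    header as line 1.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    if id_col not in raw.columns:
        raise ValueError(f"column {id_col!r} not found in {path}")
    ids = raw[id_col]
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate child_id values in {path}: {dupes}")

    out = {}
    for col in raw.columns:
        if col == id_col:
            continue
        # Python's float parser is exactly round-tripping (pandas' fast parser
        # can be off by one ulp), and lets errors name the offending cell
        values = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw[col]):
            if cell == missing_token:
                values[i] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError:
                v = float("nan")
            if not np.isfinite(v):
                raise ValueError(
                    f"unparseable cell at line {i + 2}, column {col!r}: {cell!r}"
                )
            values[i] = v
        out[col] = values

    df = pd.DataFrame(out, index=pd.Index(ids, name=id_col))
    return CohortTable(df)


def write_cohort(
    table: CohortTable,
    path: str | Path,
    missing_token: str = "NA",
) -> None:
    """Write a cohort as comma-separated text; round-trips through :func:`read_cohort`.

    Floats are written at full precision so the round-trip is lossless; column
    order is preserved.
    """
    table.data.to_csv(path, na_rep=missing_token)


def composite_score(table: CohortTable, spec: CompositeSpec) -> CohortTable:
    """Return a new table with ``spec.name`` = arithmetic mean of the components.

    The composite is missing whenever ANY component is missing, which pushes the
    complete-case decision downstream instead of silently averaging over fewer
    tests for some children.
    """
    for comp in spec.components:
        if comp not in table.data.columns:
            raise KeyError(f"unknown component column {comp!r}")
    if spec.name in table.data.columns:
        raise ValueError(f"column {spec.name!r} already exists")
    df = table.data.copy()
    df[spec.name] = df[list(spec.components)].mean(axis=1, skipna=False)
    return CohortTable(df)


def _pairwise_pearson(a: pd.Series, b: pd.Series) -> tuple[float, int]:
    """Pearson r over pairwise-complete observations; returns (r, n). NaN r if unevaluable."""
    paired = pd.concat([a, b], axis=1).dropna()
    n = len(paired)
    if n < MIN_PAIRWISE_N:
        return float("nan"), n
    x = paired.iloc[:, 0].to_numpy()
    y = paired.iloc[:, 1].to_numpy()
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan"), n
    return float(stats.pearsonr(x, y).statistic), n


def screen_predictors(
    table: CohortTable,
    candidates: Sequence[str],
    acc_col: str,
    speed_col: str,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> list[ScreeningReport]:
    """Screen candidate predictors against both reading outcomes.

    A candidate is selected iff its pairwise-complete Pearson correlation with both
    reading accuracy and reading speed is non-negative.  Within each *group* of
    alternative measures for the same construct, only the member maximizing
    ``r_accuracy + r_speed`` stays selected; an exact tie is a hard error asking
    for an explicit user choice.

    Candidates with fewer than three pairwise-complete observations (or zero
    variance) against either outcome are flagged unevaluable and not selected.
    """
    for col in (acc_col, speed_col, *candidates):
        if col not in table.data.columns:
            raise KeyError(f"unknown measure column {col!r}")

    reports: dict[str, ScreeningReport] = {}
    for cand in candidates:
        r_acc, n_acc = _pairwise_pearson(table.data[cand], table.data[acc_col])
        r_spd, n_spd = _pairwise_pearson(table.data[cand], table.data[speed_col])
        if np.isnan(r_acc) or np.isnan(r_spd):
            reports[cand] = ScreeningReport(
                cand, r_acc, r_spd, False,
                f"unevaluable: insufficient pairwise-complete data or zero variance "
                f"(n_acc={n_acc}, n_speed={n_spd})",
            )
        elif r_acc >= 0.0 and r_spd >= 0.0:
            reports[cand] = ScreeningReport(
                cand, r_acc, r_spd, True, "non-negative correlation with both outcomes"
            )
        else:
            reports[cand] = ScreeningReport(
                cand, r_acc, r_spd, False, "negative correlation with an outcome"
            )

    if groups:
        for gname, members in groups.items():
            unknown = [m for m in members if m not in reports]
            if unknown:
                raise KeyError(f"group {gname!r} names non-candidates: {unknown}")
            live = [m for m in members if reports[m].selected]
            if len(live) <= 1:
                continue
            scores = {m: reports[m].r_accuracy + reports[m].r_speed for m in live}
            best = max(scores.values())
            winners = [m for m, s in scores.items() if s == best]
            if len(winners) > 1:
                raise ValueError(
                    f"tie in group {gname!r} between {winners}; "
                    "break the tie by passing only the chosen measure"
                )
            for m in live:
                if m != winners[0]:
                    reports[m] = ScreeningReport(
                        m, reports[m].r_accuracy, reports[m].r_speed, False,
                        f"dominated within group {gname!r} by {winners[0]!r}",
                    )
    return [reports[c] for c in candidates]
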