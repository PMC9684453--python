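"""Spring temperature-window screening.

Before fixing a forcing window, the analysis screens every contiguous
1-, 2-, or 3-month mean temperature window between February and May for
its Pearson correlation with the observed event day-of-year, per forest
stratum and continent.  The March–April window is the fixed choice the
downstream model uses; the screen is a diagnostic that justifies it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import RecordSet
from .simulate import MonthlyClimateSeries

_MONTH_ABBR = {2: "Feb", 3: "Mar", 4: "Apr", 5: "May"}

MIN_GROUP_N = 3


@dataclass(frozen=True)
class WindowDef:
    """A contiguous monthly averaging window within February–May."""

    start_month: int
    length: int

    def __post_init__(self) -> None:
        if not 2 <= self.start_month <= 5:
            raise ValueError("start_month must be 2..5")
        if not 1 <= self.length <= 3:
            raise ValueError("length must be 1..3")
        if self.start_month + self.length - 1 > 5:
            raise ValueError("window extends past May")

    @property
    def months(self) -> tuple[int, ...]:
        return tuple(range(self.start_month, self.start_month + self.length))

    @property
    def label(self) -> str:
        if self.length == 1:
            return _MONTH_ABBR[self.start_month]
        return f"{_MONTH_ABBR[self.start_month]}–{_MONTH_ABBR[self.months[-1]]}"


MARCH_APRIL = WindowDef(3, 2)


def enumerate_windows() -> list[WindowDef]:
    """All 9 candidate windows (4 one-month, 3 two-month, 2 three-month),
    ordered by length then start month."""
    return [
        WindowDef(start, length)
        for length in (1, 2, 3)
        for start in range(2, 7 - length)
    ]


@dataclass
class WindowScreenResult:
    """Tidy per-(stratum, continent, window) correlation table.

    Columns: stratum, continent, window, start_month, length, r, n, note.
    ``r`` is NaN where undefined (zero temperature variance) or where the
    group is too small (n < 3); ``note`` says which.
    """

    table: pd.DataFrame

    def best_window(self, stratum: str, continent: str) -> WindowDef | None:
        """The window with the largest |r| for a group (None if all NaN)."""
        sub = self.table[
            (self.table.stratum == stratum) & (self.table.continent == continent)
        ].dropna(subset=["r"])
        if sub.empty:
            return None
        row = sub.loc[sub.r.abs().idxmax()]
        return WindowDef(int(row.start_month), int(row.length))

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def screen_windows(
    records: RecordSet, monthly: MonthlyClimateSeries
) -> WindowScreenResult:
    """Pearson r between each candidate window's mean temperature and DOY.

    Pooled within stratum×continent (the model is linear in temperature, so
    Pearson rather than rank correlation).  Groups with fewer than 3 records
    or zero temperature variance are flagged in the table, never dropped.
    Invariant to record order.
    """
    if not monthly.covers(records):
        raise ValueError("monthly series does not cover every record")
    df = records.to_dataframe()
    rows = []
    for (stratum, continent) in records.groups():
        grp = df[(df.stratum == stratum) & (df.continent == continent)]
        doy = grp.doy.to_numpy(dtype=float)
        for w in enumerate_windows():
            wmean = monthly.window_mean(w.start_month, w.length).reindex(
                grp.record_id
            ).to_numpy(dtype=float)
            r, note = _pearson(wmean, doy)
            rows.append(
                {
                    "stratum": stratum,
                    "continent": continent,
                    "window": w.label,
                    "start_month": w.start_month,
                    "length": w.length,
                    "r": r,
                    "n": len(grp),
                    "note": note,
                }
            )
    return WindowScreenResult(pd.DataFrame(rows))


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    if len(x) < MIN_GROUP_N:
        return float("nan"), "n < 3"
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), "zero variance"
    return float(np.corrcoef(x, y)[0, 1]), ""
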