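"""Sliding-window search for the temperature cue.

Given a daily temperature series and an annual response (mean laying date or
food-peak date), exhaustively scan candidate windows of days-of-year and
return the window whose across-year mean temperature correlates most strongly
(squared Pearson r) with the response.  This is a plain grid search; it does
not attempt model weighting or randomization tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class MissingDaysError(ValueError):
    def __init__(self, gaps):
        self.gaps = gaps
        super().__init__(f"temperature series missing days: {gaps[:10]}"
                         + ("..." if len(gaps) > 10 else ""))


def _doy_table(series: pd.DataFrame) -> pd.DataFrame:
    s = series.copy()
    s["date"] = pd.to_datetime(s["date"])
    if s["date"].duplicated().any():
        raise ValueError("duplicate dates in temperature series")
    s["year"] = s["date"].dt.year
    s["doy"] = s["date"].dt.dayofyear
    return s


def window_mean(series: pd.DataFrame, start_doy: int, end_doy: int, year: int) -> float:
    """Mean daily temperature over [start_doy, end_doy] (inclusive) in a year."""
    if end_doy < start_doy:
        raise ValueError("end_doy before start_doy")
    s = _doy_table(series)
    sub = s[(s["year"] == year) & (s["doy"] >= start_doy) & (s["doy"] <= end_doy)]
    want = set(range(start_doy, end_doy + 1))
    have = set(sub["doy"])
    if want - have:
        raise MissingDaysError(sorted(want - have))
    return float(sub["value"].mean())


@dataclass
class WindowSearchResult:
    start_doy: int
    end_doy: int
    r2: float
    grid: pd.DataFrame  # start_doy, end_doy, r2
    window_means: pd.Series  # by year, for the best window


def find_best_window(
    series: pd.DataFrame,
    annual_response: pd.Series,
    candidate_start_range: tuple[int, int],
    candidate_end_range: tuple[int, int],
    min_length: int = 5,
) -> WindowSearchResult:
    """Exhaustive window grid search maximizing squared Pearson correlation.

    Ties are broken by earliest start day, then shortest window.  The annual
    response is indexed by year; at least 5 years are required.
    """
    resp = pd.Series(annual_response).dropna()
    if len(resp) < 5:
        raise ValueError(f"need >= 5 years of response, got {len(resp)}")
    if float(np.std(resp)) == 0.0:
        raise ValueError("response constant: correlation undefined")
    years = np.array(sorted(resp.index))
    s = _doy_table(series)
    s = s[s["year"].isin(years)]

    s0, s1 = candidate_start_range
    e0, e1 = candidate_end_range
    doy_lo, doy_hi = s0, e1
    # per-year cumulative sums over the candidate day range
    mat = np.full((len(years), doy_hi - doy_lo + 1), np.nan)
    for k, y in enumerate(years):
        sub = s[(s["year"] == y) & (s["doy"] >= doy_lo) & (s["doy"] <= doy_hi)]
        gaps = sorted(set(range(doy_lo, doy_hi + 1)) - set(sub["doy"]))
        if gaps:
            raise MissingDaysError([f"{y}:{d}" for d in gaps])
        mat[k, sub["doy"].to_numpy() - doy_lo] = sub["value"].to_numpy()
    csum = np.concatenate(
        [np.zeros((len(years), 1)), np.cumsum(mat, axis=1)], axis=1
    )

    y_resp = resp.loc[years].to_numpy(float)
    yc = y_resp - y_resp.mean()
    ss_y = float(np.sum(yc**2))

    rows = []
    for start in range(s0, s1 + 1):
        for end in range(max(e0, start + min_length - 1), e1 + 1):
            means = (csum[:, end - doy_lo + 1] - csum[:, start - doy_lo]) / (
                end - start + 1
            )
            xc = means - means.mean()
            ss_x = float(np.sum(xc**2))
            r2 = float(np.sum(xc * yc) ** 2 / (ss_x * ss_y)) if ss_x > 0 else 0.0
            rows.append((start, end, r2))
    if not rows:
        raise ValueError("empty candidate grid: no window satisfies min_length")
    grid = pd.DataFrame(rows, columns=["start_doy", "end_doy", "r2"])
    # argmax with ties -> earliest start, then shortest window
    best = grid.sort_values(
        ["r2", "start_doy", "end_doy"], ascending=[False, True, True]
    )
    top = best[np.isclose(best["r2"], best["r2"].iloc[0])]
    top = top.assign(length=top["end_doy"] - top["start_doy"])
    top = top.sort_values(["start_doy", "length"]).iloc[0]
    start, end = int(top["start_doy"]), int(top["end_doy"])
    means = (csum[:, end - doy_lo + 1] - csum[:, start - doy_lo]) / (end - start + 1)
    return WindowSearchResult(
        start_doy=start,
        end_doy=end,
        r2=float(top["r2"]),
        grid=grid,
        window_means=pd.Series(means, index=years, name="window_mean"),
    )
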