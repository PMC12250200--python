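"""Period fruit growth, integrated water stress, and their correlation.

The integrated water-stress statistic for a period x is

    S_psi_x = | sum_i ((psi_i + psi_{i+1}) / 2 - c) * n_i |   [MPa * days]

where the sum runs over consecutive water-potential measurements starting
from the last measurement at or before the period start, ``n_i`` is the
number of days between measurements i and i+1, and ``c`` is the
unstressed baseline (-0.4 MPa by default).  This is a trapezoidal
integral of the stress deficit, taken in absolute value.

Growth over a period is measured per fruit as end-point minus start-point
diameter — caliper values are the mean of the two replicate readings of a
day, image values come from one randomly selected photograph of that day —
then averaged per tree before correlating with S_psi_x.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import STREAM_IMAGE_PICK, SimConfig, rng_for
from .scene_sim import PsiSeries

logger = logging.getLogger(__name__)

METHODS = ("caliper", "image_high", "image_low")


class CoverageError(ValueError):
    """The psi series does not span the requested period."""


@dataclass(frozen=True)
class StressGrowthRecord:
    """Per tree and period: growth by one method and integrated stress."""

    tree_id: str
    period: tuple[dt.date, dt.date]
    method: str
    growth_mm: float
    s_psi: float

    def __post_init__(self) -> None:
        if self.period[1] <= self.period[0]:
            raise ValueError("period end must follow period start")
        if self.s_psi < 0:
            raise ValueError("s_psi is an absolute value and cannot be negative")


# ---------------------------------------------------------------------------
# integrated stress
# ---------------------------------------------------------------------------

def integrated_stress(psi: PsiSeries | pd.DataFrame, period: tuple[dt.date, dt.date],
                      c: float = -0.4) -> float:
    """Integrated water stress S_psi (MPa*days) over a period.

    Accumulation starts from the last measurement at or before the period
    start and runs over consecutive measurement pairs until the first
    measurement at or after the period end; each pair contributes its
    midpoint deficit times the days it spans.  The absolute value of the
    total is returned.
    """
    if isinstance(psi, PsiSeries):
        dates, values = list(psi.dates), np.asarray(psi.psi, float)
    else:
        frame = psi.sort_values("date")
        dates = [d.date() if hasattr(d, "date") and not isinstance(d, dt.date) else d
                 for d in frame["date"]]
        values = frame["psi_MPa"].to_numpy(float)
    start, end = period
    if end <= start:
        raise ValueError("period end must follow period start")

    before = [i for i, d in enumerate(dates) if d <= start]
    if not before:
        raise CoverageError(
            f"no psi measurement at or before period start {start} "
            f"(earliest is {dates[0]})"
        )
    i = before[-1]
    if dates[-1] < end:
        raise CoverageError(
            f"no psi measurement at or after period end {end} "
            f"(latest is {dates[-1]})"
        )

    total = 0.0
    while dates[i] < end:
        n_days = (dates[i + 1] - dates[i]).days
        total += ((values[i] + values[i + 1]) / 2.0 - c) * n_days
        i += 1
    return abs(total)


# ---------------------------------------------------------------------------
# period growth
# ---------------------------------------------------------------------------

def _endpoint_value(sub: pd.DataFrame, boundary: dt.date, method: str,
                    rng: np.random.Generator) -> float | None:
    """Diameter value at (the last measurement on or before) a boundary."""
    eligible = sub[sub["date"] <= boundary]
    if eligible.empty:
        return None
    day = eligible["date"].max()
    rows = eligible[eligible["date"] == day]
    if method == "caliper":
        return float(rows["value_mm"].mean())
    # image methods: one seeded uniformly-random photograph of that day
    pick = int(rng.integers(0, len(rows)))
    return float(rows["value_mm"].to_numpy(float)[pick])


def period_growth(measurements: pd.DataFrame, period: tuple[dt.date, dt.date],
                  method: str, seed: int = 0) -> pd.DataFrame:
    """Per-tree mean fruit growth (mm) over a period for one method.

    ``measurements`` has columns (fruit_id, tree_id, date, method,
    value_mm, replicate_index).  Per fruit, the endpoint diameter is taken
    at the last measurement date on or before each period boundary —
    caliper endpoints average the two replicates, image endpoints use one
    seeded random photograph of that day.  Fruits missing an endpoint are
    excluded with a logged warning; a tree with no usable fruit raises.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    start, end = period
    if end <= start:
        raise ValueError("period end must follow period start")
    df = measurements[measurements["method"] == method]
    if df.empty:
        raise ValueError(f"no measurements for method {method!r}")

    rng = rng_for(seed, STREAM_IMAGE_PICK)
    fruit_rows = []
    for (fruit_id, tree_id), sub in df.groupby(["fruit_id", "tree_id"], sort=True):
        v0 = _endpoint_value(sub, start, method, rng)
        v1 = _endpoint_value(sub, end, method, rng)
        if v0 is None or v1 is None:
            logger.warning("fruit %s lacks a %s endpoint in period %s..%s; excluded",
                           fruit_id, method, start, end)
            continue
        fruit_rows.append((fruit_id, tree_id, v1 - v0))
    per_fruit = pd.DataFrame(fruit_rows, columns=["fruit_id", "tree_id", "growth_mm"])

    trees_in = set(df["tree_id"])
    trees_out = set(per_fruit["tree_id"])
    missing = sorted(trees_in - trees_out)
    if missing:
        raise ValueError(f"trees with zero usable fruits in period {start}..{end}: {missing}")
    return (per_fruit.groupby("tree_id", sort=True)["growth_mm"]
            .mean().reset_index())


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def build_stress_growth_records(psi_by_tree: dict[str, PsiSeries] | pd.DataFrame,
                                measurements: pd.DataFrame,
                                periods: Sequence[tuple[dt.date, dt.date]],
                                methods: Iterable[str] = METHODS,
                                c: float = -0.4, seed: int = 0) -> pd.DataFrame:
    """Assemble per-tree growth and integrated stress for every period/method."""
    if isinstance(psi_by_tree, pd.DataFrame):
        psi_by_tree = {
            tree: PsiSeries(tree_id=tree,
                            dates=[d.date() if hasattr(d, "hour") else d
                                   for d in sub.sort_values("date")["date"]],
                            psi=sub.sort_values("date")["psi_MPa"].to_numpy(float))
            for tree, sub in psi_by_tree.groupby("tree_id")
        }
    rows = []
    for period in periods:
        s_psi = {tree: integrated_stress(series, period, c=c)
                 for tree, series in psi_by_tree.items()}
        for method in methods:
            growth = period_growth(measurements, period, method, seed=seed)
            for rec in growth.itertuples(index=False):
                if rec.tree_id not in s_psi:
                    raise KeyError(f"no psi series for tree {rec.tree_id!r}")
                rows.append((rec.tree_id, period[0], period[1], method,
                             rec.growth_mm, s_psi[rec.tree_id]))
    return pd.DataFrame(rows, columns=["tree_id", "period_start", "period_end",
                                       "method", "growth_mm", "s_psi"])


def growth_stress_correlation(records: pd.DataFrame, method: str) -> pd.DataFrame:
    """OLS of per-tree growth on integrated stress, per period.

    Returns one row per period with the squared Pearson correlation,
    slope (mm per MPa*day), intercept and tree count.  Zero variance in
    either variable raises, since r2 is then undefined.
    """
    sub = records[records["method"] == method]
    if sub.empty:
        raise ValueError(f"no records for method {method!r}")
    rows = []
    for (start, end), grp in sub.groupby(["period_start", "period_end"], sort=True):
        if len(grp) < 3:
            raise ValueError(f"need >= 3 trees per period, got {len(grp)} for {start}..{end}")
        x = grp["s_psi"].to_numpy(float)
        y = grp["growth_mm"].to_numpy(float)
        if np.ptp(x) < 1e-300 or np.ptp(y) < 1e-300:
            raise ValueError(f"zero variance in period {start}..{end}: r2 undefined")
        fit = stats.linregress(x, y)
        rows.append((start, end, method, fit.rvalue ** 2, fit.slope,
                     fit.intercept, len(grp)))
    return pd.DataFrame(rows, columns=["period_start", "period_end", "method",
                                       "r2", "slope", "intercept", "n_trees"])


def default_periods(config: SimConfig) -> list[tuple[dt.date, dt.date]]:
    """Whole season plus month-boundary sub-periods within it."""
    start, end = config.season
    boundaries = [start]
    cursor = dt.date(start.year, start.month, 1)
    while True:
        cursor = (dt.date(cursor.year + 1, 1, 1) if cursor.month == 12
                  else dt.date(cursor.year, cursor.month + 1, 1))
        if cursor >= end:
            break
        if cursor > start:
            boundaries.append(cursor)
    boundaries.append(end)
    periods = [(start, end)]
    periods += [(a, b) for a, b in zip(boundaries, boundaries[1:])]
    return periods
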