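"""Ingest of discharge, temperature and limnological-profile CSVs.

The austral flow season runs December through January.  All functional
objects in the pipeline live on a single equidistant daily grid spanning
Dec 1 of the season's starting year through Jan 31 of the following year
(62 nodes, 61 one-day intervals).  Discharge is modelled on the scale
``DR = log(zeta + discharge)`` with a small positive offset ``zeta`` so
that zero-flow intervals remain finite; ``log(zeta)`` is the zero-flow
reference level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    InsufficientDataError,
    ParameterError,
)

logger = logging.getLogger(__name__)

#: default offset inside log(zeta + discharge); log(0.01) marks zero flow
DEFAULT_ZETA = 0.01

#: default stream set gauged on Lake Fryxell used throughout
DEFAULT_STREAMS = ("canada", "lost_seal", "von_guerard")


@dataclass(frozen=True)
class SeasonGrid:
    """Equidistant time grid for one flow season (Dec 1 .. Jan 31).

    Attributes
    ----------
    season_label : int
        Calendar year of the season's December.
    t : np.ndarray
        Node times ``t_0 < ... < t_M`` in days since Dec 1, equidistant.
    dt : float
        Grid spacing in days.
    """

    season_label: int
    t: np.ndarray
    dt: float

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        if t.size < 2:
            raise ParameterError("grid needs at least 2 nodes")
        steps = np.diff(t)
        if not np.allclose(steps, self.dt, rtol=0, atol=1e-9):
            raise ParameterError("grid must be equidistant with spacing dt")

    @property
    def M(self) -> int:
        """Number of intervals (nodes minus one)."""
        return self.t.size - 1

    @property
    def T(self) -> float:
        """Horizon length ``t_M - t_0`` in days."""
        return float(self.t[-1] - self.t[0])

    @property
    def n_nodes(self) -> int:
        return self.t.size

    def dates(self) -> list[date]:
        """Calendar date of every grid node."""
        start = date(self.season_label, 12, 1)
        return [start + timedelta(days=int(round(ti))) for ti in self.t]


def season_grid(
    season_label: int,
    dt: float = 1.0,
    start_month_day: tuple[int, int] = (12, 1),
    end_month_day: tuple[int, int] = (1, 31),
) -> SeasonGrid:
    """Build the daily Dec–Jan grid for one season.

    With the defaults this gives 62 nodes (M = 61, T = 61 days).
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    start = date(season_label, *start_month_day)
    end = date(season_label + 1, *end_month_day)
    span = (end - start).days
    if span <= 0:
        raise ParameterError("season window is empty")
    n_int = int(round(span / dt))
    if not np.isclose(n_int * dt, span):
        raise ParameterError("dt must divide the season span evenly")
    t = np.arange(n_int + 1) * dt
    return SeasonGrid(season_label=season_label, t=t, dt=float(dt))


@dataclass(frozen=True)
class DischargeRecord:
    stream_id: str
    timestamp: pd.Timestamp
    discharge: float
    quality_flag: str | None = None


@dataclass(frozen=True)
class LogDischargeObs:
    """Daily log-discharge observations on a subset of grid nodes."""

    stream_id: str
    season_label: int
    obs_idx: np.ndarray  # indices into the grid nodes
    values: np.ndarray  # DR_obs = log(zeta + daily mean discharge)
    zeta: float

    @property
    def L(self) -> int:
        return int(self.obs_idx.size)


@dataclass(frozen=True)
class TemperatureSeries:
    """Complete daily mean air temperature on the season grid (°C)."""

    season_label: int
    values: np.ndarray


@dataclass(frozen=True)
class LimnoProfileRecord:
    """One depth-resolved limnological measurement.

    ``ppr`` is primary production in μgC/(L·day), ``chl`` chlorophyll-A in
    μg/L; either may be absent (None).
    """

    date: date
    depth: float
    ppr: float | None = None
    chl: float | None = None


# ---------------------------------------------------------------------------
# readers


def read_discharge(path, stream_id: str) -> list[DischargeRecord]:
    """Read a discharge CSV (timestamp, discharge[, flag]) for one stream.

    Rows with unparseable or negative discharge are dropped with a logged
    count; records are returned sorted by time.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "timestamp" not in cols or "discharge" not in cols:
        raise FormatError(f"{path}: need 'timestamp' and 'discharge' columns")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    ts = pd.to_datetime(df[cols["timestamp"]], errors="coerce")
    q = pd.to_numeric(df[cols["discharge"]], errors="coerce")
    flag = df[cols["flag"]] if "flag" in cols else None
    ok = ts.notna() & q.notna() & (q >= 0)
    n_rej = int((~ok).sum())
    if n_rej:
        logger.info("read_discharge(%s): rejected %d rows", stream_id, n_rej)
    records = [
        DischargeRecord(
            stream_id=stream_id,
            timestamp=ts.iloc[i],
            discharge=float(q.iloc[i]),
            quality_flag=None if flag is None else str(flag.iloc[i]),
        )
        for i in np.flatnonzero(ok.to_numpy())
    ]
    records.sort(key=lambda r: r.timestamp)
    if not records:
        raise EmptyInputError(f"{path}: no valid rows after validation")
    return records


def write_discharge(records: Sequence[DischargeRecord], path) -> None:
    """Write records back to the CSV dialect ``read_discharge`` accepts."""
    pd.DataFrame(
        {
            "timestamp": [r.timestamp.isoformat() for r in records],
            "discharge": [r.discharge for r in records],
        }
    ).to_csv(path, index=False)


def daily_average(
    records: Sequence[DischargeRecord], grid: SeasonGrid
) -> np.ndarray:
    """Per-grid-node mean discharge; NaN where a day has no records.

    Day-boundary assignment uses the calendar date of each timestamp as
    given; no timezone arithmetic.  No imputation happens here.
    """
    out = np.full(grid.n_nodes, np.nan)
    if not records:
        return out
    day_index = {d: i for i, d in enumerate(grid.dates())}
    sums = np.zeros(grid.n_nodes)
    counts = np.zeros(grid.n_nodes, dtype=int)
    for r in records:
        i = day_index.get(r.timestamp.date())
        if i is not None:
            sums[i] += r.discharge
            counts[i] += 1
    has = counts > 0
    out[has] = sums[has] / counts[has]
    return out


def log_transform(
    daily: np.ndarray,
    zeta: float = DEFAULT_ZETA,
    *,
    stream_id: str = "",
    season_label: int = 0,
) -> LogDischargeObs:
    """Apply DR = log(zeta + discharge) to the observed nodes.

    Missing (NaN) nodes are excluded; L may be zero.
    """
    if zeta <= 0:
        raise ParameterError("zeta must be positive")
    daily = np.asarray(daily, dtype=float)
    idx = np.flatnonzero(~np.isnan(daily))
    return LogDischargeObs(
        stream_id=stream_id,
        season_label=season_label,
        obs_idx=idx,
        values=np.log(zeta + daily[idx]),
        zeta=zeta,
    )


def read_temperature(
    path, grid: SeasonGrid, max_gap_days: int = 3, max_missing_frac: float = 0.5
) -> TemperatureSeries:
    """Read daily mean air temperature and return a complete grid series.

    Internal gaps of at most ``max_gap_days`` consecutive days are filled by
    linear interpolation (fill count logged); longer gaps, edge gaps, or more
    than ``max_missing_frac`` of nodes missing raise
    :class:`InsufficientDataError`.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "date" not in cols or "mean_temp_c" not in cols:
        raise FormatError(f"{path}: need 'date' and 'mean_temp_c' columns")
    d = pd.to_datetime(df[cols["date"]], errors="coerce").dt.date
    v = pd.to_numeric(df[cols["mean_temp_c"]], errors="coerce")
    by_date = {dd: vv for dd, vv in zip(d, v) if dd is not None and not np.isnan(vv)}
    vals = np.array([by_date.get(dd, np.nan) for dd in grid.dates()])
    return _complete_temperature(vals, grid, max_gap_days, max_missing_frac)


def _complete_temperature(
    vals: np.ndarray, grid: SeasonGrid, max_gap_days: int, max_missing_frac: float
) -> TemperatureSeries:
    missing = np.isnan(vals)
    if missing.mean() > max_missing_frac:
        raise InsufficientDataError(
            f"temperature: {missing.mean():.0%} of grid days missing"
        )
    if missing.any():
        # reject edge gaps and internal runs longer than max_gap_days
        if missing[0] or missing[-1]:
            raise InsufficientDataError("temperature: missing at season edges")
        run = 0
        for m in missing:
            run = run + 1 if m else 0
            if run > max_gap_days:
                raise InsufficientDataError(
                    f"temperature gap exceeds {max_gap_days} days"
                )
        filled = np.interp(grid.t, grid.t[~missing], vals[~missing])
        logger.info("read_temperature: filled %d missing days", missing.sum())
        vals = filled
    return TemperatureSeries(season_label=grid.season_label, values=vals)


def read_limno_profiles(path) -> list[LimnoProfileRecord]:
    """Read limnological profiles (date, depth_m, ppr, chl).

    At least one of the ppr/chl columns must be present.  Rows with invalid
    depth or negative measurements are dropped with a logged count; duplicate
    (date, depth) rows are kept — aggregation happens downstream.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "date" not in cols or "depth_m" not in cols:
        raise FormatError(f"{path}: need 'date' and 'depth_m' columns")
    if "ppr" not in cols and "chl" not in cols:
        raise FormatError(f"{path}: need at least one of 'ppr'/'chl'")
    d = pd.to_datetime(df[cols["date"]], errors="coerce")
    depth = pd.to_numeric(df[cols["depth_m"]], errors="coerce")
    ppr = (
        pd.to_numeric(df[cols["ppr"]], errors="coerce")
        if "ppr" in cols
        else pd.Series(np.nan, index=df.index)
    )
    chl = (
        pd.to_numeric(df[cols["chl"]], errors="coerce")
        if "chl" in cols
        else pd.Series(np.nan, index=df.index)
    )
    records: list[LimnoProfileRecord] = []
    n_rej = 0
    for i in range(len(df)):
        if pd.isna(d.iloc[i]) or pd.isna(depth.iloc[i]) or depth.iloc[i] <= 0:
            n_rej += 1
            continue
        p = None if pd.isna(ppr.iloc[i]) else float(ppr.iloc[i])
        c = None if pd.isna(chl.iloc[i]) else float(chl.iloc[i])
        if (p is not None and p < 0) or (c is not None and c < 0):
            n_rej += 1
            continue
        if p is None and c is None:
            n_rej += 1
            continue
        records.append(
            LimnoProfileRecord(
                date=d.iloc[i].date(), depth=float(depth.iloc[i]), ppr=p, chl=c
            )
        )
    if n_rej:
        logger.info("read_limno_profiles: rejected %d rows", n_rej)
    return records
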