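"""Read, validate, regularize and summarize CGM traces.

Canonical CSV dialect: comma-separated, header
``patient_id,timestamp,glucose_mmol_l,calibration_bg_mmol_l``,
ISO-8601 UTC timestamps at second resolution.  Readings are in mmol/L
throughout; an mg/dL ingest option converts by dividing by 18.016.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DuplicateTimestampError,
    EmptyInputError,
    FormatError,
    InsufficientDataError,
    ParameterError,
)

logger = logging.getLogger(__name__)

MG_DL_PER_MMOL_L = 18.016


@dataclass
class CsvDialect:
    """Column mapping for CGM CSV files."""

    patient_col: str = "patient_id"
    time_col: str = "timestamp"
    glucose_col: str = "glucose_mmol_l"
    calibration_col: str | None = "calibration_bg_mmol_l"
    units: str = "mmol/L"  # or "mg/dL" (converted at ingest)


@dataclass
class GlucoseSeries:
    """Timestamped glucose trace for one patient.

    ``timestamps`` is a strictly increasing ``datetime64[s]`` array;
    ``glucose`` holds finite positive mmol/L values; ``calibration_bg`` is
    NaN where no sensor-calibration entry exists.
    """

    patient_id: str
    timestamps: np.ndarray
    glucose: np.ndarray
    calibration_bg: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.glucose = np.asarray(self.glucose, dtype=np.float64)
        if self.calibration_bg is None:
            self.calibration_bg = np.full(self.glucose.shape, np.nan)
        else:
            self.calibration_bg = np.asarray(self.calibration_bg, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        n = len(self.timestamps)
        if len(self.glucose) != n or len(self.calibration_bg) != n:
            raise ParameterError("per-sample columns must have equal length")
        if n == 0:
            return
        diffs = np.diff(self.timestamps.astype("int64"))
        if np.any(diffs == 0):
            at = self.timestamps[1:][diffs == 0][0]
            raise DuplicateTimestampError(f"duplicate timestamp at {at}")
        if np.any(diffs < 0):
            raise ParameterError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.glucose)):
            raise ParameterError("glucose values must be finite")
        if np.any(self.glucose <= 0):
            raise ParameterError("glucose values must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class SeriesSummary:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    n_calibration: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "mean_mmol_l": self.mean,
                "sd_mmol_l": self.sd,
                "min_mmol_l": self.min,
                "max_mmol_l": self.max,
                "n_calibration": self.n_calibration,
            },
            indent=2,
        )


def read_cgm_csv(path, dialect: CsvDialect | None = None) -> GlucoseSeries:
    """Read one patient's trace from CSV; unparseable glucose rows are
    dropped (and counted in the log), duplicate timestamps are an error."""
    dialect = dialect or CsvDialect()
    df = pd.read_csv(path)
    required = [dialect.time_col, dialect.glucose_col]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")

    glucose = pd.to_numeric(df[dialect.glucose_col], errors="coerce")
    times = pd.to_datetime(df[dialect.time_col], errors="coerce", utc=True)
    ok = glucose.notna() & times.notna() & (glucose > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d unparseable/invalid rows", path, n_dropped)
    df = df[ok]
    if len(df) == 0:
        raise EmptyInputError(f"no valid rows in {path}")

    glucose = glucose[ok].to_numpy(dtype=np.float64)
    if dialect.units == "mg/dL":
        glucose = glucose / MG_DL_PER_MMOL_L
    elif dialect.units != "mmol/L":
        raise ParameterError(f"unknown units {dialect.units!r}")

    ts = times[ok].dt.tz_localize(None).to_numpy().astype("datetime64[s]")
    order = np.argsort(ts, kind="stable")
    ts, glucose = ts[order], glucose[order]

    if dialect.calibration_col and dialect.calibration_col in df.columns:
        cal = pd.to_numeric(df[dialect.calibration_col], errors="coerce").to_numpy()
        cal = cal[order]
        if dialect.units == "mg/dL":
            cal = cal / MG_DL_PER_MMOL_L
    else:
        cal = None

    if dialect.patient_col in df.columns and len(df) > 0:
        patient_id = str(df[dialect.patient_col].iloc[0])
    else:
        patient_id = "unknown"

    return GlucoseSeries(patient_id, ts, glucose, cal)


def write_cgm_csv(series: GlucoseSeries, path) -> str:
    """Write in the canonical dialect; round-trips via read_cgm_csv
    (timestamps to the second, glucose to 4 decimal places)."""
    if len(series) == 0:
        raise EmptyInputError("refusing to write an empty series")
    series.validate()
    cal = pd.array(np.round(series.calibration_bg, 4))
    df = pd.DataFrame(
        {
            "patient_id": series.patient_id,
            "timestamp": np.datetime_as_string(series.timestamps, unit="s"),
            "glucose_mmol_l": np.round(series.glucose, 4),
            "calibration_bg_mmol_l": cal,
        }
    )
    df.to_csv(path, index=False, float_format="%.4f")
    return str(path)


def regularize(
    series: GlucoseSeries, interval_min: int = 5, max_gap_min: int = 15
) -> list[GlucoseSeries]:
    """Snap a trace to an exact ``interval_min`` grid.

    Gaps of at most ``max_gap_min`` are filled by linear interpolation;
    longer gaps split the series into separate segments.  Segments shorter
    than 2 samples are discarded.
    """
    if interval_min <= 0:
        raise ParameterError("interval_min must be positive")
    if max_gap_min < interval_min:
        raise ParameterError("max_gap_min must be >= interval_min")
    if len(series) == 0:
        raise EmptyInputError("cannot regularize an empty series")

    step = np.timedelta64(interval_min * 60, "s")
    t = series.timestamps
    # snap each observation to the grid anchored at the first sample
    offsets = (t - t[0]) / step
    snapped = t[0] + np.round(offsets.astype(np.float64)).astype(np.int64) * step

    # where snapping collides, keep the first occurrence
    _, keep = np.unique(snapped, return_index=True)
    keep.sort()
    snapped = snapped[keep]
    glucose = series.glucose[keep]
    cal = series.calibration_bg[keep]

    gap_steps = np.diff(snapped) / step  # integer number of grid steps
    max_fill = max_gap_min // interval_min
    split_at = np.where(gap_steps > max_fill)[0] + 1

    segments: list[GlucoseSeries] = []
    for idx, (lo, hi) in enumerate(
        zip(np.r_[0, split_at], np.r_[split_at, len(snapped)])
    ):
        seg_t, seg_g, seg_c = snapped[lo:hi], glucose[lo:hi], cal[lo:hi]
        if len(seg_t) < 2:
            continue
        # fill interior gaps (≤ max_fill steps) by linear interpolation
        n_steps = int((seg_t[-1] - seg_t[0]) / step)
        grid = seg_t[0] + np.arange(n_steps + 1) * step
        xs = ((seg_t - seg_t[0]) / step).astype(np.float64)
        grid_x = np.arange(n_steps + 1, dtype=np.float64)
        filled_g = np.interp(grid_x, xs, seg_g)
        filled_c = np.full(len(grid), np.nan)
        filled_c[np.isin(grid, seg_t)] = _reindex(seg_t, seg_c, grid)
        segments.append(
            GlucoseSeries(series.patient_id, grid, filled_g, filled_c)
        )
    if not segments:
        raise EmptyInputError("no segment of length >= 2 after regularization")
    return segments


def _reindex(src_t: np.ndarray, src_v: np.ndarray, grid: np.ndarray) -> np.ndarray:
    pos = {int(t.astype("int64")): v for t, v in zip(src_t, src_v)}
    mask = np.isin(grid, src_t)
    return np.array([pos[int(t.astype("int64"))] for t in grid[mask]])


def summarize(series: GlucoseSeries) -> SeriesSummary:
    """Exact sample statistics of the glucose column (sd uses n−1)."""
    g = series.glucose
    if len(g) < 2:
        raise InsufficientDataError("need at least 2 samples for sample sd")
    return SeriesSummary(
        n=len(g),
        mean=float(np.mean(g)),
        sd=float(np.std(g, ddof=1)),
        min=float(np.min(g)),
        max=float(np.max(g)),
        n_calibration=int(np.sum(~np.isnan(series.calibration_bg))),
    )


def pooled_summary(cohort: list[GlucoseSeries]) -> SeriesSummary:
    """Summary over all glucose values pooled across a cohort."""
    if not cohort:
        raise EmptyInputError("empty cohort")
    g = np.concatenate([s.glucose for s in cohort])
    cal = np.concatenate([s.calibration_bg for s in cohort])
    if len(g) < 2:
        raise InsufficientDataError("need at least 2 samples for sample sd")
    return SeriesSummary(
        n=len(g),
        mean=float(np.mean(g)),
        sd=float(np.std(g, ddof=1)),
        min=float(np.min(g)),
        max=float(np.max(g)),
        n_calibration=int(np.sum(~np.isnan(cal))),
    )
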