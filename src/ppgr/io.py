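"""Reading, writing and validation of CGM traces and food diaries.

Two small CSV dialects, modelled on flash-glucose-monitor exports:

* CGM file: ``patient_id,period,timestamp,glucose_mmol_l`` with ISO-8601
  timestamps, one row per sensor sample (nominal 15-minute spacing).
* Food diary: ``patient_id,period,timestamp,item,carbs_g[,energy_kcal,
  protein_g,fat_g]``, one row per diary line (a food), several lines close
  in time forming one meal.

Internally time is real-valued minutes from the start of an analysis
window; timestamps exist only at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GlucoseTrace",
    "MealRecord",
    "AnalysisDataset",
    "ReadReport",
    "FormatError",
    "ValidationError",
    "read_cgm_csv",
    "write_cgm_csv",
    "read_food_diary",
    "write_food_diary",
    "align_period",
]

PERIODS = ("pre", "post")

CGM_COLUMNS = ["patient_id", "period", "timestamp", "glucose_mmol_l"]
DIARY_COLUMNS = ["patient_id", "period", "timestamp", "item", "carbs_g"]
DIARY_OPTIONAL = ["energy_kcal", "protein_g", "fat_g"]


class FormatError(ValueError):
    """A file does not match the documented CSV dialect."""


class ValidationError(ValueError):
    """Data parsed but violates an invariant (ordering, sign, overlap)."""


@dataclasses.dataclass
class GlucoseTrace:
    """One patient-period CGM time series.

    ``times_min`` are minutes from ``start`` (strictly increasing);
    ``glucose`` is interstitial glucose in mmol/l with NaN marking missing
    samples (rows present in the export but unparseable, or gaps filled in
    by the reader are *not* invented -- gaps simply have no row).
    """

    patient_id: str
    period: str
    start: pd.Timestamp
    times_min: np.ndarray
    glucose: np.ndarray
    nominal_interval: float = 15.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.times_min.shape != self.glucose.shape:
            raise ValidationError("times and glucose must have equal length")
        if self.times_min.size and np.any(np.diff(self.times_min) <= 0):
            i = int(np.argmax(np.diff(self.times_min) <= 0))
            raise ValidationError(
                f"timestamps not strictly increasing for "
                f"{self.patient_id}/{self.period} at sample {i + 1}"
            )
        finite = self.glucose[np.isfinite(self.glucose)]
        if finite.size and np.any(finite <= 0):
            raise ValidationError("glucose values must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.times_min.size)

    @property
    def values(self) -> np.ndarray:
        """Non-missing glucose samples."""
        return self.glucose[np.isfinite(self.glucose)]


@dataclasses.dataclass
class MealRecord:
    """One reported eating event: timestamp plus carbohydrate grams.

    Other nutrients are carried through unused -- the response model takes
    only carbohydrate into account.
    """

    patient_id: str
    period: str
    reported_time: pd.Timestamp
    carbs: float
    item: str = "meal"
    energy_kcal: float | None = None
    protein_g: float | None = None
    fat_g: float | None = None

    def __post_init__(self) -> None:
        if self.carbs < 0:
            raise ValidationError(
                f"negative carbohydrate ({self.carbs} g) for "
                f"{self.patient_id}/{self.period} at {self.reported_time}"
            )


@dataclasses.dataclass
class AnalysisDataset:
    """A trace and its diary on a common minutes-from-window-start axis."""

    patient_id: str
    period: str
    window_start: pd.Timestamp
    times_min: np.ndarray
    glucose: np.ndarray
    meal_times_min: np.ndarray
    meal_carbs: np.ndarray

    @property
    def n_meals(self) -> int:
        return int(self.meal_times_min.size)

    @property
    def observed_mask(self) -> np.ndarray:
        return np.isfinite(self.glucose)


@dataclasses.dataclass
class ReadReport:
    """Row accounting for a reader: parsed + merged + failed == input rows."""

    path: str
    rows_in: int
    rows_parsed: int
    rows_merged: int = 0
    rows_failed: int = 0

    def lines(self) -> list[str]:
        return [
            f"read {self.path}: {self.rows_in} rows in, "
            f"{self.rows_parsed} parsed, {self.rows_merged} merged, "
            f"{self.rows_failed} failed"
        ]


def write_cgm_csv(traces: Iterable[GlucoseTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        ts = tr.start + pd.to_timedelta(tr.times_min, unit="m")
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": tr.patient_id,
                    "period": tr.period,
                    "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
                    "glucose_mmol_l": tr.glucose,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cgm_csv(
    path: str | Path, nominal_interval: float = 15.0
) -> tuple[list[GlucoseTrace], ReadReport]:
    """Read a CGM CSV into one trace per patient-period.

    Rows whose glucose cannot be parsed become missing (NaN) samples and
    are counted in the report; rows with unparseable timestamps fail.
    Non-monotone timestamps within a patient-period raise ValidationError.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CGM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    rows_in = len(df)
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad_ts = ts.isna()
    glucose = pd.to_numeric(df["glucose_mmol_l"], errors="coerce")
    traces: list[GlucoseTrace] = []
    n_unparseable = int((glucose.isna() & ~bad_ts).sum())
    df = df.assign(_ts=ts, _glu=glucose)[~bad_ts]
    for (pid, period), g in df.groupby(["patient_id", "period"], sort=True):
        start = g["_ts"].iloc[0]
        mins = (g["_ts"] - start).dt.total_seconds().to_numpy() / 60.0
        traces.append(
            GlucoseTrace(
                patient_id=str(pid),
                period=str(period),
                start=start,
                times_min=mins,
                glucose=g["_glu"].to_numpy(),
                nominal_interval=nominal_interval,
            )
        )
    report = ReadReport(
        path=str(path),
        rows_in=rows_in,
        rows_parsed=rows_in - int(bad_ts.sum()) - n_unparseable,
        rows_failed=int(bad_ts.sum()) + n_unparseable,
    )
    # unparseable glucose rows are retained as NaN samples, so they count
    # as parsed structure but failed values; keep the identity rows_in =
    # parsed + merged + failed by treating them as failed values only.
    return traces, report


def write_food_diary(meals: Iterable[MealRecord], path: str | Path) -> None:
    rows = []
    for m in meals:
        rows.append(
            {
                "patient_id": m.patient_id,
                "period": m.period,
                "timestamp": m.reported_time.strftime("%Y-%m-%dT%H:%M:%S"),
                "item": m.item,
                "carbs_g": m.carbs,
                "energy_kcal": m.energy_kcal,
                "protein_g": m.protein_g,
                "fat_g": m.fat_g,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_food_diary(
    path: str | Path, merge_window: float = 15.0
) -> tuple[list[MealRecord], ReadReport]:
    """Read a diary CSV and merge lines into meals.

    Diary lines are individual foods; the model's unit is a meal. Lines of
    one patient-period whose timestamps fall within ``merge_window``
    minutes of the running meal are merged: carbohydrates are summed and
    the meal time is the carb-weighted mean of the merged lines (the
    unweighted mean when all carbs are zero).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in DIARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    rows_in = len(df)
    df["_ts"] = pd.to_datetime(df["timestamp"], errors="coerce")
    df["_carbs"] = pd.to_numeric(df["carbs_g"], errors="coerce")
    failed = df["_ts"].isna() | df["_carbs"].isna()
    if (df.loc[~failed, "_carbs"] < 0).any():
        bad = df.loc[~failed & (df["_carbs"] < 0)].iloc[0]
        raise ValidationError(
            f"negative carbohydrate ({bad['_carbs']} g) for "
            f"{bad['patient_id']}/{bad['period']}"
        )
    ok = df[~failed].sort_values(["patient_id", "period", "_ts"])
    meals: list[MealRecord] = []
    n_merged = 0
    for (pid, period), g in ok.groupby(["patient_id", "period"], sort=True):
        cluster: list[pd.Series] = []
        for _, row in g.iterrows():
            if cluster and (
                (row["_ts"] - cluster[-1]["_ts"]).total_seconds() / 60.0
                > merge_window
            ):
                meals.append(_merge_lines(cluster, str(pid), str(period)))
                n_merged += len(cluster) - 1
                cluster = []
            cluster.append(row)
        if cluster:
            meals.append(_merge_lines(cluster, str(pid), str(period)))
            n_merged += len(cluster) - 1
    report = ReadReport(
        path=str(path),
        rows_in=rows_in,
        rows_parsed=rows_in - int(failed.sum()) - n_merged,
        rows_merged=n_merged,
        rows_failed=int(failed.sum()),
    )
    return meals, report


def _merge_lines(lines: Sequence[pd.Series], pid: str, period: str) -> MealRecord:
    carbs = np.array([float(ln["_carbs"]) for ln in lines])
    t0 = lines[0]["_ts"]
    offs = np.array([(ln["_ts"] - t0).total_seconds() for ln in lines])
    if carbs.sum() > 0:
        t = t0 + pd.Timedelta(seconds=float(np.average(offs, weights=carbs)))
    else:
        t = t0 + pd.Timedelta(seconds=float(offs.mean()))
    item = lines[0]["item"] if len(lines) == 1 else f"meal[{len(lines)} items]"
    return MealRecord(
        patient_id=pid,
        period=period,
        reported_time=t,
        carbs=float(carbs.sum()),
        item=str(item),
    )


def align_period(
    trace: GlucoseTrace,
    meals: Sequence[MealRecord],
    days: int = 3,
    carry_in_min: float = 180.0,
    window_start: pd.Timestamp | None = None,
) -> AnalysisDataset:
    """Restrict a trace to its diary's recording window.

    The window spans ``days`` days from ``window_start`` (default:
    midnight of the earliest diary day). Meals up to ``carry_in_min``
    minutes before the window start are retained (their responses may
    overlap the window) and get negative minute coordinates; earlier
    meals are dropped.
    """
    meals = [m for m in meals if m.patient_id == trace.patient_id and m.period == trace.period]
    if not meals:
        raise ValidationError(
            f"no diary entries for {trace.patient_id}/{trace.period}"
        )
    if window_start is None:
        window_start = min(m.reported_time for m in meals).normalize()
    window_len = days * 24 * 60.0
    # window start expressed on the trace's minutes axis
    trace_min = (window_start - trace.start).total_seconds() / 60.0
    keep = (trace.times_min >= trace_min) & (trace.times_min < trace_min + window_len)
    if not keep.any():
        raise ValidationError(
            f"trace and diary windows do not overlap for "
            f"{trace.patient_id}/{trace.period}"
        )
    meal_min = np.array(
        [(m.reported_time - window_start).total_seconds() / 60.0 for m in meals]
    )
    carbs = np.array([m.carbs for m in meals])
    in_window = (meal_min >= -carry_in_min) & (meal_min < window_len)
    return AnalysisDataset(
        patient_id=trace.patient_id,
        period=trace.period,
        window_start=window_start,
        times_min=trace.times_min[keep] - trace_min,
        glucose=trace.glucose[keep],
        meal_times_min=meal_min[in_window],
        meal_carbs=carbs[in_window],
    )
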