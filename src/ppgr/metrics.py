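"""Glycemic-profile metrics: time in range, trace summaries, histograms.

Band percentages are taken over non-missing samples only ("wear time"),
with half-open bands [a, b): a sample exactly at 4.0 mmol/l counts as
in-range, not hypoglycaemic.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GlucoseTrace

__all__ = [
    "DEFAULT_BAND_EDGES",
    "GlycemicSummary",
    "time_in_bands",
    "band_labels",
    "trace_summary",
    "aggregate_histogram",
]

DEFAULT_BAND_EDGES = (4.0, 5.0, 6.0, 7.0)  # mmol/l


@dataclasses.dataclass
class GlycemicSummary:
    """Per-trace profile: mean/min/max, CV and time-in-band percentages."""

    patient_id: str
    period: str
    mean: float
    minimum: float
    maximum: float
    cv: float  # percent, sd (n-1) / mean
    time_in_band: dict[str, float]  # percent per band, sums to 100
    r_squared: float | None = None

    def as_row(self) -> dict[str, float | str | None]:
        row: dict[str, float | str | None] = {
            "patient_id": self.patient_id,
            "period": self.period,
            "mean_mmol_l": self.mean,
            "min_mmol_l": self.minimum,
            "max_mmol_l": self.maximum,
            "cv_percent": self.cv,
        }
        for k, v in self.time_in_band.items():
            row[f"pct_{k}"] = v
        row["r_squared_percent"] = self.r_squared
        return row


def band_labels(edges: Sequence[float] = DEFAULT_BAND_EDGES) -> list[str]:
    labels = [f"lt_{edges[0]:g}"]
    labels += [f"{a:g}_to_{b:g}" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f"ge_{edges[-1]:g}")
    return labels


def _values(trace: GlucoseTrace | np.ndarray) -> np.ndarray:
    x = trace.glucose if isinstance(trace, GlucoseTrace) else np.asarray(trace, float)
    return x[np.isfinite(x)]


def time_in_bands(
    trace: GlucoseTrace | np.ndarray,
    edges: Sequence[float] = DEFAULT_BAND_EDGES,
) -> dict[str, float]:
    """Percent of wear time per glucose band.

    ``edges`` (strictly increasing, mmol/l) split the axis into
    len(edges)+1 half-open bands (-inf, e0), [e0, e1), ..., [e_last, inf).
    Each non-missing sample lands in exactly one band; percentages are of
    the non-missing count and sum to 100.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.size == 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be non-empty and strictly increasing")
    vals = _values(trace)
    if vals.size == 0:
        raise ValueError("trace has no non-missing samples")
    idx = np.searchsorted(edges, vals, side="right")  # [a,b) bands
    counts = np.bincount(idx, minlength=edges.size + 1)
    pct = 100.0 * counts / vals.size
    return dict(zip(band_labels(edges), pct))


def trace_summary(
    trace: GlucoseTrace,
    edges: Sequence[float] = DEFAULT_BAND_EDGES,
    r_squared: float | None = None,
) -> GlycemicSummary:
    """Table-style summary of one trace over its non-missing samples.

    CV is 100 * sd / mean with the n-1 (sample) standard deviation.  Min
    and max are raw observations, never fitted values.
    """
    vals = _values(trace)
    if vals.size < 2:
        raise ValueError("need at least two non-missing samples")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    return GlycemicSummary(
        patient_id=trace.patient_id,
        period=trace.period,
        mean=mean,
        minimum=float(np.min(vals)),
        maximum=float(np.max(vals)),
        cv=100.0 * sd / mean,
        time_in_band=time_in_bands(trace, edges),
        r_squared=r_squared,
    )


def aggregate_histogram(
    traces: Iterable[GlucoseTrace],
    bin_width: float = 0.25,
) -> pd.DataFrame:
    """Normalized histogram of all samples pooled across individuals.

    Samples are pooled (not per-patient averaged) and binned at
    ``bin_width`` mmol/l; heights are densities, so
    sum(height * bin_width) == 1.  Returns columns
    ``bin_left, bin_right, density``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    pooled = np.concatenate([_values(tr) for tr in traces])
    if pooled.size == 0:
        raise ValueError("no samples to aggregate")
    lo = np.floor(pooled.min() / bin_width) * bin_width
    hi = np.ceil(pooled.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    dens, edges = np.histogram(pooled, bins=edges, density=True)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "density": dens}
    )


def summaries_frame(summaries: Iterable[GlycemicSummary]) -> pd.DataFrame:
    """Stack per-trace summaries into a tidy frame (one row per trace)."""
    return pd.DataFrame([s.as_row() for s in summaries])
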