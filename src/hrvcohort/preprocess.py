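"""RR-interval ingestion, eligibility rules, artifact filtering, and tachogram resampling.

The raw material of every HRV statistic is the sequence of intervals between
consecutive normal (sinus) heartbeats. Ambulatory Holter recorders export RR
intervals that still contain ectopic beats and detection artifacts; these must
be removed before any marker is meaningful. This module reads plain-text RR
exports, applies cohort eligibility rules (pacemaker, predominant atrial
fibrillation, heart transplant), filters the RR series to a normal-to-normal
(NN) series, and resamples the NN series onto a uniform time grid (the
"tachogram") as required by spectral estimators.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import interp1d

__all__ = [
    "RRSeries",
    "RecordMeta",
    "NNSeries",
    "Tachogram",
    "FilterParams",
    "Eligibility",
    "read_rr_text",
    "write_rr_text",
    "check_eligibility",
    "filter_to_nn",
    "resample_tachogram",
]

BEAT_LABELS = ("normal", "ectopic", "artifact", "af")


class RRParseError(ValueError):
    """Raised when an RR text file cannot be parsed."""


class EmptySeriesError(ValueError):
    """Raised when an operation would produce or consume an empty beat series."""


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested computation."""


@dataclass
class RRSeries:
    """Raw RR intervals for one recording.

    intervals are in milliseconds; beat_times are cumulative seconds from the
    start of the recording (time of each beat, i.e. the end of its interval).
    """

    record_id: str
    intervals: np.ndarray
    beat_times: np.ndarray | None = None
    labels: np.ndarray | None = None  # per-beat annotation from BEAT_LABELS

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if self.intervals.size and np.any(self.intervals <= 0):
            raise ValueError("all RR intervals must be positive")
        if self.beat_times is not None:
            self.beat_times = np.asarray(self.beat_times, dtype=float)
            if len(self.beat_times) != len(self.intervals):
                raise ValueError("beat_times and intervals must have equal length")
            if self.beat_times.size > 1 and np.any(np.diff(self.beat_times) <= 0):
                raise ValueError("beat_times must be strictly increasing")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.intervals):
                raise ValueError("labels and intervals must have equal length")

    def __len__(self) -> int:
        return int(self.intervals.size)

    def with_times(self) -> "RRSeries":
        """Return a copy whose beat_times are filled (cumulative sum of intervals)."""
        if self.beat_times is not None:
            return self
        times = np.cumsum(self.intervals) / 1000.0
        return RRSeries(self.record_id, self.intervals, times, self.labels)


@dataclass
class RecordMeta:
    """Per-recording metadata used by the eligibility rules."""

    record_id: str
    has_pacemaker: bool = False
    af_fraction: float = 0.0
    heart_transplant: bool = False
    wearing_time_h: float = 24.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.af_fraction <= 1.0:
            raise ValueError(
                f"af_fraction must lie in [0, 1], got {self.af_fraction!r}"
            )
        if self.wearing_time_h < 0:
            raise ValueError("wearing_time_h must be non-negative")


@dataclass
class NNSeries:
    """Normal-to-normal interval series after artifact filtering."""

    record_id: str
    intervals: np.ndarray
    beat_times: np.ndarray
    rejected_count: int = 0

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if len(self.intervals) != len(self.beat_times):
            raise ValueError("intervals and beat_times must have equal length")
        if self.intervals.size and np.any(self.intervals <= 0):
            raise ValueError("NN intervals must be positive")
        if self.beat_times.size > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def duration_s(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass
class Tachogram:
    """NN intervals resampled onto a uniform grid (ms), for spectral analysis."""

    values: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.rate

    @property
    def duration_s(self) -> float:
        return (len(self) - 1) / self.rate if len(self) else 0.0


@dataclass
class FilterParams:
    """Artifact filter settings.

    A beat is rejected when its interval falls outside ``abs_bounds``, when it
    carries a non-normal annotation, or when it deviates from the running
    median of the previously accepted ``window_beats`` intervals by more than
    ``rel_threshold`` (fractional).
    """

    rel_threshold: float = 0.2
    window_beats: int = 11
    abs_bounds: tuple[float, float] = (300.0, 2000.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.rel_threshold < 1.0:
            raise ValueError("rel_threshold must lie in (0, 1)")
        if self.window_beats < 3 or self.window_beats % 2 == 0:
            raise ValueError("window_beats must be odd and >= 3")
        if not self.abs_bounds[0] < self.abs_bounds[1]:
            raise ValueError("abs_bounds must be increasing")


@dataclass
class Eligibility:
    """Outcome of the cohort eligibility check."""

    included: bool
    reason: str | None = None  # names the triggering exclusion rule

    def __bool__(self) -> bool:
        return self.included


def read_rr_text(
    path: str | Path,
    dialect: Literal["intervals_ms", "time_interval_csv"] = "intervals_ms",
    record_id: str | None = None,
) -> RRSeries:
    """Read a plain-text RR recording.

    ``intervals_ms``: one interval in milliseconds per line (beat times
    reconstructed as cumulative sums). ``time_interval_csv``: two columns
    ``time_s, rr_ms`` with an optional header.
    """
    path = Path(path)
    rid = record_id if record_id is not None else path.stem
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    if dialect == "intervals_ms":
        intervals = []
        for i, ln in enumerate(lines, start=1):
            if not ln or ln.startswith("#"):
                continue
            try:
                intervals.append(float(ln))
            except ValueError:
                raise RRParseError(f"{path}: non-numeric RR value at line {i}: {ln!r}")
        if not intervals:
            raise EmptySeriesError(f"{path}: no RR intervals found")
        return RRSeries(rid, np.asarray(intervals)).with_times()
    elif dialect == "time_interval_csv":
        times, intervals = [], []
        rows = list(csv.reader([ln for ln in lines if ln]))
        for i, row in enumerate(rows, start=1):
            if len(row) < 2:
                raise RRParseError(f"{path}: expected two columns at line {i}")
            try:
                t, rr = float(row[0]), float(row[1])
            except ValueError:
                if i == 1:  # tolerate a header row
                    continue
                raise RRParseError(f"{path}: non-numeric value at line {i}: {row!r}")
            times.append(t)
            intervals.append(rr)
        if not intervals:
            raise EmptySeriesError(f"{path}: no RR intervals found")
        return RRSeries(rid, np.asarray(intervals), np.asarray(times))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_rr_text(series: RRSeries | NNSeries, path: str | Path) -> None:
    """Write intervals in the one-interval-per-line millisecond format."""
    path = Path(path)
    path.write_text("\n".join(f"{v:.6g}" for v in series.intervals) + "\n")


def check_eligibility(meta: RecordMeta) -> Eligibility:
    """Apply the cohort exclusion rules to one recording.

    Excluded when the participant has pacemaker stimulation, when atrial
    fibrillation covers at least half of the recording time, or after heart
    transplantation.
    """
    if meta.has_pacemaker:
        return Eligibility(False, "pacemaker")
    if meta.af_fraction >= 0.5:
        return Eligibility(False, "af")
    if meta.heart_transplant:
        return Eligibility(False, "heart_transplant")
    return Eligibility(True)


def filter_to_nn(rr: RRSeries, params: FilterParams | None = None) -> NNSeries:
    """Filter an RR series to normal-to-normal intervals.

    Sequential pass: a beat is accepted when it lies inside the absolute
    bounds, carries no non-normal annotation, and deviates from the running
    median of the most recently accepted ``window_beats`` intervals by at most
    ``rel_threshold``. The running reference is built from accepted beats
    only, which makes the filter idempotent.
    """
    if len(rr) == 0:
        raise EmptySeriesError("cannot filter an empty RR series")
    params = params or FilterParams()
    rr = rr.with_times()
    lo, hi = params.abs_bounds
    w = params.window_beats

    accepted_vals: list[float] = []
    accepted_times: list[float] = []
    for i in range(len(rr)):
        x = rr.intervals[i]
        if rr.labels is not None and rr.labels[i] != "normal":
            continue
        if not lo <= x <= hi:
            continue
        recent = accepted_vals[-w:]
        if len(recent) >= 2:
            ref = float(np.median(recent))
            if abs(x - ref) / ref > params.rel_threshold:
                continue
        accepted_vals.append(float(x))
        accepted_times.append(float(rr.beat_times[i]))

    if not accepted_vals:
        raise EmptySeriesError(
            f"{rr.record_id}: artifact filter rejected every beat"
        )
    return NNSeries(
        rr.record_id,
        np.asarray(accepted_vals),
        np.asarray(accepted_times),
        rejected_count=len(rr) - len(accepted_vals),
    )


def resample_tachogram(
    nn: NNSeries,
    rate: float = 4.0,
    method: Literal["linear", "cubic"] = "linear",
) -> Tachogram:
    """Interpolate the NN interval function onto a uniform grid.

    The NN value is treated as a function of beat time and interpolated at
    ``rate`` Hz over [first beat, last beat]. 4 Hz is the conventional rate
    for HRV spectral analysis (Nyquist 2 Hz, well above the respiratory band).
    """
    if len(nn) < 2:
        raise InsufficientDataError("resampling needs at least two beats")
    if rate <= 0:
        raise ValueError("rate must be positive")
    t0, t1 = nn.beat_times[0], nn.beat_times[-1]
    n = int(np.floor((t1 - t0) * rate)) + 1
    grid = t0 + np.arange(n) / rate
    kind = {"linear": "linear", "cubic": "cubic"}[method]
    if kind == "cubic" and len(nn) < 4:
        kind = "linear"
    f = interp1d(nn.beat_times, nn.intervals, kind=kind, assume_sorted=True)
    return Tachogram(values=f(grid), rate=rate, start_time=float(t0))
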