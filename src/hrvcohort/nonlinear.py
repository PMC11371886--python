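"""Non-linear HRV markers.

Seven markers computed on the NN interval sequence in beat domain (the
resampled tachogram would smooth away beat-to-beat dynamics):

* acceleration capacity (AC) and deceleration capacity (DC) via
  phase-rectified signal averaging (PRSA) — anchor-aligned averaging of the
  interval series around heart-rate accelerations/decelerations, summarised
  by a Haar-like contrast of the averaged profile;
* time lag — smallest shift at which the series decorrelates from itself
  (autocorrelation criterion);
* embedding dimension — Cao's method on the delay reconstruction;
* fractal (correlation) dimension — Grassberger–Procaccia D2;
* sample entropy — Richman–Moorman SampEn(m, r);
* maximal Lyapunov exponent — Rosenstein's nearest-neighbour divergence
  method with a fixed neighbourhood radius (100 ms by default, reflecting
  the marker's conventional "r=100" parameterisation).

Markers that cannot be computed raise :class:`MarkerUndefined` carrying a
reason code; the marker-table layer records these as explicit missing
values, never zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .preprocess import InsufficientDataError, NNSeries

__all__ = [
    "NonlinearParams",
    "PRSAProfile",
    "MarkerUndefined",
    "LagEstimate",
    "DimEstimate",
    "prsa_capacity",
    "time_lag",
    "embedding_dimension",
    "correlation_dimension",
    "sample_entropy",
    "max_lyapunov",
    "nonlinear_markers",
]


class MarkerUndefined(ValueError):
    """A marker could not be computed; ``reason`` is a short machine code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass
class NonlinearParams:
    """Tunable settings for the non-linear estimators.

    ``lyap_radius`` is in the units of the series (ms for NN intervals).
    ``theiler_window`` (temporal exclusion for neighbour searches) defaults
    to the estimated time lag when None. ``max_points`` caps the number of
    points entering the O(n^2) estimators; longer series are truncated to
    their leading segment.
    """

    prsa_L: int = 2
    prsa_max_rel_change: float = 0.05
    acf_threshold: float = 1.0 / math.e
    max_lag: int = 50
    cao_threshold: float = 0.95
    max_dim: int = 15
    sampen_m: int = 2
    sampen_r_frac: float = 0.2
    lyap_radius: float = 100.0
    lyap_fit_range: tuple[int, int] = (1, 10)
    theiler_window: int | None = None
    max_points: int = 5000

    def __post_init__(self) -> None:
        if not 0.0 < self.sampen_r_frac < 1.0:
            raise ValueError("sampen_r_frac must lie in (0, 1)")
        for name in ("prsa_L", "max_lag", "max_dim", "sampen_m", "max_points"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PRSAProfile:
    window_offsets: np.ndarray  # beat offsets -L .. L-1 relative to the anchor
    profile: np.ndarray  # mean NN at each offset (ms)
    anchor_count: int
    direction: str


@dataclass
class LagEstimate:
    lag: int
    saturated: bool = False  # autocorrelation never crossed the threshold

    def __int__(self) -> int:
        return self.lag

    def __index__(self) -> int:
        return self.lag


@dataclass
class DimEstimate:
    dim: int
    saturated: bool = False  # E1 never levelled off below max_dim
    e1: np.ndarray | None = None
    e2: np.ndarray | None = None

    def __int__(self) -> int:
        return self.dim

    def __index__(self) -> int:
        return self.dim


def _as_array(series) -> np.ndarray:
    if isinstance(series, NNSeries):
        return np.asarray(series.intervals, dtype=float)
    return np.asarray(series, dtype=float)


def _truncate(x: np.ndarray, p: NonlinearParams) -> np.ndarray:
    return x[: p.max_points] if len(x) > p.max_points else x


def _embed(x: np.ndarray, m: int, lag: int) -> np.ndarray:
    """Delay reconstruction: rows (x_i, x_{i+lag}, ..., x_{i+(m-1)lag})."""
    n = len(x) - (m - 1) * lag
    if n < 1:
        raise InsufficientDataError("series too short for this embedding")
    idx = np.arange(n)[:, None] + lag * np.arange(m)[None, :]
    return x[idx]


# ---------------------------------------------------------------------------
# PRSA acceleration / deceleration capacity


def prsa_capacity(
    nn,
    direction: Literal["deceleration", "acceleration"] = "deceleration",
    p: NonlinearParams | None = None,
) -> tuple[float, PRSAProfile]:
    """Phase-rectified signal averaging capacity.

    Anchors are beats where the interval lengthens (deceleration) or
    shortens (acceleration) relative to the previous beat; anchors whose
    relative change exceeds ``prsa_max_rel_change`` are discarded as likely
    artifacts, as are anchors whose +/-L beat window leaves the series.
    The averaged profile X(k) over offsets k = -L..L-1 is summarised by the
    Haar-like contrast (X(0) + X(1) - X(-1) - X(-2)) / 4: positive for DC
    (parasympathetic, heart-rate slowing), negative for AC (sympathetic).
    """
    p = p or NonlinearParams()
    x = _as_array(nn)
    L = p.prsa_L
    if L < 2:
        raise ValueError("prsa_L must be >= 2 (the capacity uses offsets -2..1)")
    if len(x) < 2 * L + 2:
        raise InsufficientDataError("PRSA needs at least 2L+2 beats")
    prev = x[:-1]
    cur = x[1:]
    if direction == "deceleration":
        is_anchor = cur > prev
    elif direction == "acceleration":
        is_anchor = cur < prev
    else:
        raise ValueError(f"unknown direction {direction!r}")
    is_anchor &= np.abs(cur - prev) <= p.prsa_max_rel_change * prev
    anchors = np.nonzero(is_anchor)[0] + 1  # anchor index into x
    anchors = anchors[(anchors >= L) & (anchors + L - 1 <= len(x) - 1)]
    if anchors.size == 0:
        raise MarkerUndefined("no_anchors", f"no valid {direction} anchors")
    offsets = np.arange(-L, L)
    windows = x[anchors[:, None] + offsets[None, :]]
    profile = windows.mean(axis=0)
    k0 = L  # position of offset 0 in the profile
    capacity = (profile[k0] + profile[k0 + 1] - profile[k0 - 1] - profile[k0 - 2]) / 4.0
    return float(capacity), PRSAProfile(offsets, profile, int(anchors.size), direction)


# ---------------------------------------------------------------------------
# Time lag (ACF decorrelation)


def _sample_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation for lags 0..max_lag."""
    x = x - x.mean()
    denom = float(np.dot(x, x))
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for k in range(1, max_lag + 1):
        acf[k] = float(np.dot(x[:-k], x[k:])) / denom
    return acf


def time_lag(nn, p: NonlinearParams | None = None) -> LagEstimate:
    """Smallest lag at which the autocorrelation falls below the threshold.

    Default threshold is 1/e. A long time lag signals a sluggish, poorly
    modulated heart rhythm: the series must be shifted further before
    carrying independent information.
    """
    p = p or NonlinearParams()
    x = _as_array(nn)
    if len(x) < p.max_lag + 2:
        raise InsufficientDataError("series too short for the requested max_lag")
    if np.std(x) == 0:
        raise MarkerUndefined("zero_variance", "autocorrelation undefined")
    acf = _sample_acf(x, p.max_lag)
    below = np.nonzero(acf[1:] < p.acf_threshold)[0]
    if below.size == 0:
        return LagEstimate(p.max_lag, saturated=True)
    return LagEstimate(int(below[0] + 1))


# ---------------------------------------------------------------------------
# Cao's embedding dimension


def _cao_statistics(
    y_d: np.ndarray, y_d1: np.ndarray, last_col: np.ndarray, floor: float
) -> tuple[float, float]:
    """Cao's E(d) and E*(d) for one dimension.

    E(d) is the mean ratio of (d+1)- to d-dimensional Chebyshev distance to
    the d-dimensional nearest neighbour; E*(d) is the mean absolute
    difference of the next delayed coordinate between each point and that
    neighbour. Neighbours closer than ``floor`` are skipped: exact or
    float-identical recurrences (periodic signals, repeated values) would
    otherwise produce ratios dominated by rounding noise.
    """
    n = len(y_d1)
    y_d = y_d[:n]
    tree = cKDTree(y_d)
    k = min(n, 20)
    dist, idx = tree.query(y_d, k=k, p=np.inf)
    rows = np.arange(n)[:, None]
    valid = (idx != rows) & (dist > floor)
    has = valid.any(axis=1)
    if not has.any():
        raise MarkerUndefined("degenerate_series", "no usable neighbours")
    first = np.argmax(valid, axis=1)  # first valid neighbour per row
    i_idx = np.nonzero(has)[0]
    j_idx = idx[i_idx, first[i_idx]]
    den = dist[i_idx, first[i_idx]]
    num = np.max(np.abs(y_d1[i_idx] - y_d1[j_idx]), axis=1)
    nexts = np.abs(last_col[i_idx] - last_col[j_idx])
    return float(np.mean(num / den)), float(np.mean(nexts))


def embedding_dimension(
    series, lag: int, p: NonlinearParams | None = None
) -> DimEstimate:
    """Minimum embedding dimension by Cao's method.

    E1(d) = E(d+1)/E(d) with E(d) the mean nearest-neighbour distance ratio
    between the (d+1)- and d-dimensional reconstructions. Returns the
    smallest d with E1(d) >= cao_threshold and |E1(d+1) - E1(d)| below
    1 - cao_threshold. Cao's companion statistic E2 (mean next-coordinate
    distance ratio) separates deterministic signals from noise: when E2
    stays at 1 across all dimensions the series is noise-like, E1's slow
    drift towards 1 carries no dimension information, and the estimate
    saturates at max_dim with a flag.
    """
    p = p or NonlinearParams()
    lag = int(lag)
    x = _truncate(_as_array(series), p)
    if len(x) < (p.max_dim + 1) * lag + 10:
        raise InsufficientDataError("series too short for Cao's method at max_dim")
    floor = 1e-9 * float(np.std(x)) if np.std(x) > 0 else 0.0
    E = {}
    Estar = {}
    for d in range(1, p.max_dim + 2):
        y_d = _embed(x, d, lag)
        y_d1 = _embed(x, d + 1, lag)
        last_col = y_d1[:, -1]
        E[d], Estar[d] = _cao_statistics(y_d, y_d1, last_col, floor)
    e1 = np.array([E[d + 1] / E[d] for d in range(1, p.max_dim + 1)])  # E1(1..max_dim)
    e2 = np.array([Estar[d + 1] / Estar[d] for d in range(1, p.max_dim + 1)])
    tol = 1.0 - p.cao_threshold
    # noise gate: E2 flat at 1 AND the next coordinate is unpredictable from
    # the current neighbourhood (E* on the scale of the series SD). The
    # second condition keeps quasi-periodic signals, whose E2 is also flat
    # but whose E* is tiny, on the deterministic path.
    noise_like = np.all(np.abs(e2 - 1.0) < tol) and Estar[1] > 0.1 * float(np.std(x))
    if noise_like:
        return DimEstimate(p.max_dim, saturated=True, e1=e1, e2=e2)
    for d in range(1, p.max_dim):
        if e1[d - 1] >= p.cao_threshold and abs(e1[d] - e1[d - 1]) < tol:
            return DimEstimate(d, saturated=False, e1=e1, e2=e2)
    return DimEstimate(p.max_dim, saturated=True, e1=e1, e2=e2)


# ---------------------------------------------------------------------------
# Grassberger-Procaccia correlation dimension


def correlation_sums(
    y: np.ndarray, radii: np.ndarray, theiler: int
) -> np.ndarray:
    """C(r): fraction of point pairs (|i-j| > theiler) within chebyshev r."""
    n = len(y)
    radii = np.asarray(radii, dtype=float)
    bins = np.concatenate(([0.0], radii))
    hist = np.zeros(len(radii))
    total = 0
    chunk = max(1, int(2e6 // max(n, 1)))
    for start in range(0, n, chunk):
        rows = y[start : start + chunk]
        d = np.max(np.abs(rows[:, None, :] - y[None, :, :]), axis=2)
        i_idx = np.arange(start, start + len(rows))[:, None]
        j_idx = np.arange(n)[None, :]
        valid = (j_idx - i_idx) > theiler  # each unordered pair counted once
        total += int(valid.sum())
        hist += np.histogram(d[valid], bins=bins)[0]
    if total == 0:
        raise MarkerUndefined("no_pairs", "Theiler window excludes every pair")
    # cumulative counts of d < r (a distance equal to r falls in the next bin)
    return np.cumsum(hist) / total


def correlation_dimension(
    series,
    m: int,
    lag: int,
    radii: Sequence[float] | None = None,
    p: NonlinearParams | None = None,
    fit_bounds: tuple[float, float] = (0.0025, 0.25),
) -> float:
    """Correlation (fractal) dimension D2 by the Grassberger-Procaccia method.

    Correlation sums C(r) are computed over log-spaced radii with a Theiler
    window suppressing temporally correlated pairs; D2 is the least-squares
    slope of log C(r) against log r over the scaling region, taken as the
    radii where C(r) falls within ``fit_bounds`` (small enough to probe fine
    structure, large enough to be populated).
    """
    p = p or NonlinearParams()
    m, lag = int(m), int(lag)
    x = _truncate(_as_array(series), p)
    if len(x) < (m - 1) * lag + 2:
        raise InsufficientDataError("series too short for this embedding")
    y = _embed(x, m, lag)
    theiler = p.theiler_window if p.theiler_window is not None else lag
    sd = float(np.std(x))
    if sd == 0:
        return 0.0
    if radii is None:
        radii = np.logspace(np.log10(0.01 * sd), np.log10(2.0 * sd), 24)
    return correlation_dimension_points(y, np.asarray(radii, float), theiler, fit_bounds)


def correlation_dimension_points(
    points: np.ndarray,
    radii: np.ndarray,
    theiler: int,
    fit_bounds: tuple[float, float] = (0.0025, 0.25),
) -> float:
    """D2 from already-embedded points (slope of log C(r) vs log r)."""
    C = correlation_sums(points, radii, theiler)
    positive = C > 0
    if positive.sum() < 3:
        raise MarkerUndefined("no_scaling_region", "fewer than 3 radii populated")
    lo, hi = fit_bounds
    in_region = positive & (C >= lo) & (C <= hi)
    if in_region.sum() < 3:
        # fall back to the populated radii below the upper bound
        in_region = positive & (C <= hi)
    if in_region.sum() < 3:
        in_region = positive
    slope = np.polyfit(np.log(radii[in_region]), np.log(C[in_region]), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Sample entropy


def sample_entropy(series, p: NonlinearParams | None = None) -> float:
    """SampEn(m, r): -ln(A/B) with A, B the counts of (m+1)- and m-template
    matches under Chebyshev distance <= r, self-matches excluded.

    r defaults to ``sampen_r_frac`` times the sample SD of the series.
    """
    p = p or NonlinearParams()
    x = _truncate(_as_array(series), p)
    m = p.sampen_m
    if len(x) <= m + 1:
        raise InsufficientDataError("series too short for sample entropy")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise MarkerUndefined("zero_variance", "tolerance r would be zero")
    r = p.sampen_r_frac * sd
    n_templates = len(x) - m  # templates of both lengths indexed 0..n_templates-1
    tm = _embed(x, m, 1)[:n_templates]
    tm1 = _embed(x, m + 1, 1)  # has exactly n_templates rows
    B = 0
    A = 0
    chunk = max(1, int(2e6 // max(n_templates, 1)))
    for start in range(0, n_templates, chunk):
        rows_m = tm[start : start + chunk]
        rows_m1 = tm1[start : start + chunk]
        d_m = np.max(np.abs(rows_m[:, None, :] - tm[None, :, :]), axis=2)
        d_m1 = np.max(np.abs(rows_m1[:, None, :] - tm1[None, :, :]), axis=2)
        i_idx = np.arange(start, start + len(rows_m))[:, None]
        j_idx = np.arange(n_templates)[None, :]
        upper = j_idx > i_idx
        B += int(np.sum((d_m <= r) & upper))
        A += int(np.sum((d_m1 <= r) & upper))
    if B == 0:
        raise MarkerUndefined("no_template_matches", "no m-length matches")
    if A == 0:
        raise MarkerUndefined("no_extended_matches", "no (m+1)-length matches")
    return float(-math.log(A / B))


# ---------------------------------------------------------------------------
# Rosenstein maximal Lyapunov exponent


def max_lyapunov(
    series, m: int, lag: int, p: NonlinearParams | None = None
) -> float:
    """Maximal Lyapunov exponent (per beat) by Rosenstein's method.

    Each embedded point is paired with its nearest neighbour lying within
    ``lyap_radius`` (Euclidean) and outside the Theiler window; the exponent
    is the least-squares slope of the mean log divergence of those pairs
    over ``lyap_fit_range`` iterations.
    """
    p = p or NonlinearParams()
    m, lag = int(m), int(lag)
    x = _truncate(_as_array(series), p)
    y = _embed(x, m, lag)
    n = len(y)
    kmax = p.lyap_fit_range[1]
    if n <= kmax + 1:
        raise InsufficientDataError("series too short for divergence tracking")
    theiler = p.theiler_window if p.theiler_window is not None else lag
    tree = cKDTree(y)
    kq = min(n, 2 * theiler + 8)
    dist, idx = tree.query(y, k=kq)
    pairs = []
    for i in range(n - kmax):
        for dd, jj in zip(dist[i], idx[i]):
            if jj == i or abs(int(jj) - i) <= theiler:
                continue
            if dd > p.lyap_radius:
                break  # neighbours are sorted; none closer will follow
            if dd > 0 and jj < n - kmax:
                pairs.append((i, int(jj)))
            break
    if len(pairs) < 0.1 * (n - kmax):
        raise MarkerUndefined(
            "no_neighbours",
            f"neighbours within radius {p.lyap_radius} for "
            f"{len(pairs)}/{n - kmax} points only",
        )
    pairs = np.asarray(pairs)
    ks = np.arange(p.lyap_fit_range[0], kmax + 1)
    mean_logs = np.empty(len(ks))
    for t, k in enumerate(ks):
        di = np.linalg.norm(y[pairs[:, 0] + k] - y[pairs[:, 1] + k], axis=1)
        good = di > 0
        if not np.any(good):
            raise MarkerUndefined("degenerate_divergence", f"all zero at step {k}")
        mean_logs[t] = float(np.mean(np.log(di[good])))
    slope = np.polyfit(ks, mean_logs, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Orchestration


def nonlinear_markers(
    nn, p: NonlinearParams | None = None
) -> tuple[dict[str, float | None], dict[str, str]]:
    """All seven non-linear marker columns for one NN series.

    Returns (values, reasons): ``values`` maps column name to the marker or
    None; ``reasons`` records why a marker is missing.
    """
    p = p or NonlinearParams()
    values: dict[str, float | None] = {}
    reasons: dict[str, str] = {}

    def attempt(name, fn):
        try:
            values[name] = fn()
        except (MarkerUndefined, InsufficientDataError) as exc:
            values[name] = None
            reasons[name] = getattr(exc, "reason", "insufficient_data")

    attempt("ac", lambda: prsa_capacity(nn, "acceleration", p)[0])
    attempt("dc", lambda: prsa_capacity(nn, "deceleration", p)[0])
    attempt("time_lag", lambda: float(time_lag(nn, p).lag))
    lag = int(values["time_lag"]) if values.get("time_lag") else 1
    attempt("embedding_dim", lambda: float(embedding_dimension(nn, lag, p).dim))
    dim = int(values["embedding_dim"]) if values.get("embedding_dim") else 2
    attempt("fractal_dim", lambda: correlation_dimension(nn, dim, lag, p=p))
    attempt("sample_entropy", lambda: sample_entropy(nn, p))
    attempt("max_lyapunov", lambda: max_lyapunov(nn, dim, lag, p))
    return values, reasons
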