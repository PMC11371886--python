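"""Time-domain HRV markers: mean HR, SDNN, SDANN, rMSSD, pNN50.

All statistics are computed on the filtered NN series. Sample (n-1)
standard deviations are used throughout. Mean heart rate is derived from the
mean NN interval (60000 / mean NN), not from beat-wise instantaneous rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import InsufficientDataError, NNSeries

__all__ = ["TimeDomainMarkers", "time_domain_markers"]


@dataclass
class TimeDomainMarkers:
    mean_hr: float  # beats/min
    sdnn: float  # ms
    sdann: float | None  # ms; None when fewer than 2 valid 5-min segments
    rmssd: float  # ms
    pnn50: float  # percent

    def as_dict(self) -> dict[str, float | None]:
        return {
            "mean_hr": self.mean_hr,
            "sdnn": self.sdnn,
            "sdann": self.sdann,
            "rmssd": self.rmssd,
            "pnn50": self.pnn50,
        }


def _sdann(
    nn: NNSeries, segment_len: float, min_segment_fill: float
) -> float | None:
    """SD of per-segment mean NN over consecutive elapsed-time windows.

    Segments start at the first accepted beat. A segment is kept only when
    the summed interval time inside it reaches ``min_segment_fill`` of the
    segment length (gaps from rejected beats would otherwise bias the mean).
    """
    rel_t = nn.beat_times - nn.beat_times[0]
    seg_idx = np.floor_divide(rel_t, segment_len).astype(int)
    means = []
    for seg in np.unique(seg_idx):
        mask = seg_idx == seg
        covered_ms = float(np.sum(nn.intervals[mask]))
        if covered_ms / 1000.0 >= min_segment_fill * segment_len:
            means.append(float(np.mean(nn.intervals[mask])))
    if len(means) < 2:
        return None
    return float(np.std(means, ddof=1))


def time_domain_markers(
    nn: NNSeries,
    segment_len: float = 300.0,
    min_segment_fill: float = 0.5,
) -> TimeDomainMarkers:
    """Compute the five time-domain markers from an NN series.

    mean_hr = 60000 / mean(NN); sdnn = sample SD of NN; sdann = sample SD of
    5-min segment means; rmssd = root mean square of successive differences;
    pnn50 = percentage of successive differences strictly exceeding 50 ms.
    """
    x = nn.intervals
    if x.size < 2:
        raise InsufficientDataError("time-domain markers need at least 2 intervals")
    diffs = np.diff(x)
    return TimeDomainMarkers(
        mean_hr=60000.0 / float(np.mean(x)),
        sdnn=float(np.std(x, ddof=1)),
        sdann=_sdann(nn, segment_len, min_segment_fill),
        rmssd=float(math.sqrt(np.mean(diffs**2))),
        pnn50=100.0 * float(np.mean(np.abs(diffs) > 50.0)),
    )
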