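"""Synthetic RR recordings and cohorts with known ground truth.

No public Holter cohort with linked survival follow-up exists for this kind
of analysis, so every pipeline stage is validated against data generated
here. Two layers:

* :func:`gen_rr_record` emulates a 24 h normal-to-normal interval series in
  beat domain: a base interval plus LF (~0.1 Hz, baroreflex-like) and HF
  (~0.25 Hz, respiratory-like) sinusoidal modulation, a 24 h circadian
  cosine supplying ULF power, AR(1) beat-to-beat noise, and optional ectopy
  (short/long compensatory interval pairs) and artifacts (spurious sub-300
  ms intervals).
* :func:`gen_cohort` draws a cohort of subjects (covariates, group label,
  marker values or full RR recordings) whose survival times follow a
  Weibull proportional-hazards model with configurable log-hazard
  coefficients per marker z-score, administratively censored at 8 years.

Everything is deterministic given the seed; the ground truth used by the
generator is returned (and written) separately from anything the pipeline
estimates.

Default amplitudes are set so a healthy synthetic subject lands near the
middle of published healthy Holter distributions (SDNN ~ 100-140 ms, LF and
HF band powers of a few hundred ms^2, ULF dominating total power); the
heart-failure group has uniformly reduced modulation and more ectopy.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RRSeries

__all__ = [
    "RRGenParams",
    "CohortGenParams",
    "CohortBundle",
    "gen_rr_record",
    "gen_chaotic_series",
    "gen_cohort",
]


@dataclass
class RRGenParams:
    """Beat-domain generator settings (intervals in ms, frequencies in Hz)."""

    duration_h: float = 22.49  # typical ambulatory Holter wearing time
    mean_nn: float = 780.0
    a_lf: float = 25.0
    f_lf: float = 0.1
    a_hf: float = 15.0
    f_hf: float = 0.25
    a_circ: float = 110.0  # 24 h cosine amplitude; the source of ULF power
    ar_coef: float = 0.9  # slow beat-to-beat noise, mostly below the LF band
    ar_sigma: float = 6.0
    ectopy_rate: float = 0.0
    artifact_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mean_nn <= self.a_lf + self.a_hf + self.a_circ:
            raise ValueError(
                "mean_nn must exceed the summed modulation amplitudes "
                "(intervals must stay positive)"
            )
        for r in (self.ectopy_rate, self.artifact_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must lie in [0, 1)")
        if not 0.0 <= abs(self.ar_coef) < 1.0:
            raise ValueError("ar_coef must be stationary (|coef| < 1)")


def gen_rr_record(p: RRGenParams, record_id: str = "synthetic") -> RRSeries:
    """Generate one RR recording.

    Beat times are built iteratively: the k-th interval is the modulation
    model evaluated at the current beat time plus AR(1) noise. Ectopic
    events replace an interval by a (0.6x, 1.4x) early/compensatory pair;
    artifact events inject a spurious short interval. Labels mark every beat
    normal / ectopic / artifact.
    """
    rng = np.random.default_rng(p.seed)
    total_s = p.duration_h * 3600.0
    est_beats = int(total_s / (p.mean_nn / 1000.0) * 1.1) + 10
    # AR(1) innovations drawn up-front for speed; the beat loop stays scalar
    innov = rng.normal(0.0, p.ar_sigma, size=est_beats)
    u_ect = rng.random(est_beats)
    u_art = rng.random(est_beats)
    art_len = rng.uniform(100.0, 280.0, size=est_beats)

    intervals: list[float] = []
    labels: list[str] = []
    t = 0.0
    eps = 0.0
    k = 0
    two_pi = 2.0 * math.pi
    while t < total_s and k < est_beats:
        eps = p.ar_coef * eps + innov[k]
        nn = (
            p.mean_nn
            + p.a_lf * math.sin(two_pi * p.f_lf * t)
            + p.a_hf * math.sin(two_pi * p.f_hf * t)
            + p.a_circ * math.cos(two_pi * t / 86400.0)
            + eps
        )
        if nn <= 0:
            raise ValueError(
                "generator produced a non-positive interval; reduce noise or "
                "modulation amplitudes"
            )
        if u_ect[k] < p.ectopy_rate:
            intervals.extend([0.6 * nn, 1.4 * nn])
            labels.extend(["ectopic", "ectopic"])
            t += 2.0 * nn / 1000.0
        elif u_art[k] < p.artifact_rate:
            intervals.extend([art_len[k], nn])
            labels.extend(["artifact", "normal"])
            t += (art_len[k] + nn) / 1000.0
        else:
            intervals.append(nn)
            labels.append("normal")
            t += nn / 1000.0
        k += 1
    series = RRSeries(
        record_id,
        np.asarray(intervals),
        labels=np.asarray(labels, dtype=object),
    )
    return series.with_times()


def gen_chaotic_series(
    map_name: str, params: tuple, n: int, x0: float = 0.2, burn_in: int = 1000
) -> np.ndarray:
    """Iterates of a chaotic map, for validating the non-linear estimators.

    ``logistic``: x -> r x (1 - x) with params (r,); ``henon``: the x
    coordinate of the Henon map with params (a, b).
    """
    if n < 100:
        raise ValueError("n must be at least 100")
    if map_name == "logistic":
        (r,) = params
        x = float(x0)
        out = np.empty(n)
        for i in range(burn_in + n):
            x = r * x * (1.0 - x)
            if not np.isfinite(x) or abs(x) > 1e6:
                raise ValueError("divergent orbit")
            if i >= burn_in:
                out[i - burn_in] = x
        return out
    if map_name == "henon":
        a, b = params
        x, y = float(x0), 0.0
        out = np.empty(n)
        for i in range(burn_in + n):
            x, y = 1.0 - a * x * x + y, b * x
            if not np.isfinite(x) or abs(x) > 1e6:
                raise ValueError("divergent orbit")
            if i >= burn_in:
                out[i - burn_in] = x
        return out
    raise ValueError(f"unknown map {map_name!r}")


# ---------------------------------------------------------------------------
# Cohort generation

# (healthy, heart-failure) normal distributions per marker, loosely matching
# published healthy/heart-failure Holter distributions
_DEFAULT_MARKER_DISTS = {
    "ac": ((-6.2, 1.9), (-4.9, 2.0)),
    "dc": ((6.4, 1.4), (5.0, 1.4)),
    "sdnn": ((136.0, 40.0), (125.0, 42.0)),
    "lf_hf": ((2.9, 1.7), (2.0, 1.2)),
}


@dataclass
class CohortGenParams:
    """Cohort-level generator settings.

    ``record_mode='markers'`` draws marker values directly from the
    group-specific normal distributions in ``marker_dists`` (fast; used for
    statistical experiments that condition on marker values);
    ``record_mode='full'`` generates an RR recording per subject from the
    group-specific :class:`RRGenParams`. Survival times follow a Weibull
    proportional-hazards model whose linear predictor is the sum of
    ``log_hr_per_sd[marker] * z`` with z the marker's z-score under its own
    group's generating distribution.
    """

    n_subjects: int = 300
    healthy_fraction: float = 0.3
    record_mode: str = "markers"
    marker_dists: dict = field(default_factory=lambda: dict(_DEFAULT_MARKER_DISTS))
    rr_healthy: RRGenParams = field(default_factory=RRGenParams)
    rr_hf: RRGenParams = field(
        default_factory=lambda: RRGenParams(
            mean_nn=830.0, a_lf=12.0, a_hf=8.0, a_circ=80.0,
            ar_sigma=5.0, ectopy_rate=0.01, artifact_rate=0.002,
        )
    )
    age_mean: float = 64.5
    age_sd: float = 10.5
    female_fraction: float = 0.354
    risk_factor_prevalence: dict = field(
        default_factory=lambda: {
            "hypertension": 0.74, "diabetes": 0.21, "dyslipidemia": 0.75,
            "smoking": 0.11, "obesity": 0.32, "cad": 0.44, "ckd": 0.24,
        }
    )
    weibull_shape: float = 1.2
    weibull_scale: float = 38.0  # years; ~14% baseline mortality by 8 years
    log_hr_per_sd: dict = field(
        default_factory=lambda: {"ac": math.log(1.53), "dc": math.log(0.70)}
    )
    censor_years: float = 8.0
    cardiac_fraction: float = 0.3
    cardiac_censor_years: float = 6.0
    pacemaker_rate: float = 0.02
    af_excluded_rate: float = 0.02
    transplant_rate: float = 0.003
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.healthy_fraction <= 1.0:
            raise ValueError("healthy_fraction must lie in [0, 1]")
        if self.record_mode not in ("markers", "full"):
            raise ValueError("record_mode must be 'markers' or 'full'")
        for v in self.log_hr_per_sd.values():
            if not np.isfinite(v):
                raise ValueError("log-hazard coefficients must be finite")


@dataclass
class CohortBundle:
    """Everything a downstream analysis needs, plus the generating truth."""

    covariates: pd.DataFrame
    markers: pd.DataFrame | None
    records: dict[str, RRSeries]
    meta: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        from .preprocess import write_rr_text

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.covariates.to_csv(outdir / "covariates.csv", index=False)
        self.meta.to_csv(outdir / "meta.csv", index=False)
        if self.markers is not None:
            self.markers.to_csv(outdir / "markers_truth.csv", index=False)
        if self.records:
            rr_dir = outdir / "rr"
            rr_dir.mkdir(exist_ok=True)
            for rid, series in self.records.items():
                write_rr_text(series, rr_dir / f"{rid}.txt")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))


def _jitter_rr_params(base: RRGenParams, rng, seed: int) -> RRGenParams:
    """Subject-level variation around the group RR parameters."""
    return dataclasses.replace(
        base,
        mean_nn=base.mean_nn + rng.normal(0.0, 40.0),
        a_lf=base.a_lf * rng.lognormal(0.0, 0.25),
        a_hf=base.a_hf * rng.lognormal(0.0, 0.25),
        a_circ=base.a_circ * rng.lognormal(0.0, 0.2),
        ar_sigma=base.ar_sigma * rng.lognormal(0.0, 0.15),
        seed=seed,
    )


def gen_cohort(p: CohortGenParams) -> CohortBundle:
    """Generate a cohort bundle (covariates, markers or recordings, truth).

    Survival: T = scale * (-ln U / exp(lp))^(1/shape) with lp the configured
    linear predictor; administrative censoring at ``censor_years``. Cardiac
    death is a configurable fraction of deaths, censored at
    ``cardiac_censor_years``.
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_subjects
    healthy = rng.random(n) < p.healthy_fraction
    age = rng.normal(p.age_mean, p.age_sd, size=n)
    sex = (rng.random(n) < p.female_fraction).astype(int)  # 1 = female
    risk = {
        name: (rng.random(n) < prev).astype(int)
        for name, prev in p.risk_factor_prevalence.items()
    }

    # marker values and their generating z-scores
    marker_names = list(p.marker_dists)
    marker_vals = np.empty((n, len(marker_names)))
    marker_z = np.empty_like(marker_vals)
    for j, m in enumerate(marker_names):
        (mu_h, sd_h), (mu_f, sd_f) = p.marker_dists[m]
        mu = np.where(healthy, mu_h, mu_f)
        sd = np.where(healthy, sd_h, sd_f)
        z = rng.normal(0.0, 1.0, size=n)
        marker_z[:, j] = z
        marker_vals[:, j] = mu + sd * z

    lp = np.zeros(n)
    for m, beta in p.log_hr_per_sd.items():
        if m not in marker_names:
            raise ValueError(f"log_hr_per_sd names unknown marker {m!r}")
        lp += beta * marker_z[:, marker_names.index(m)]

    u = rng.random(n)
    t_raw = p.weibull_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / p.weibull_shape)
    event = (t_raw <= p.censor_years).astype(int)
    time = np.minimum(t_raw, p.censor_years)
    if event.sum() == 0:
        raise ValueError(
            "generated cohort has zero events; increase n_subjects, the "
            "follow-up, or the baseline hazard (or change the seed)"
        )
    cardiac = (rng.random(n) < p.cardiac_fraction) & (event == 1)
    event_cardiac = (cardiac & (t_raw <= p.cardiac_censor_years)).astype(int)
    time_cardiac = np.minimum(t_raw, p.cardiac_censor_years)

    ids = [f"s{i:05d}" for i in range(n)]
    stages = np.where(
        healthy,
        rng.choice(["0", "A"], size=n),
        rng.choice(["B", "C"], size=n, p=[0.35, 0.65]),
    )
    covariates = pd.DataFrame(
        {
            "record_id": ids,
            "group": np.where(healthy, "healthy", "heart_failure"),
            "hf_stage": stages,
            "age": age,
            "sex": sex,
            **risk,
            "diabetes_10y_untreated": (rng.random(n) < 0.01).astype(int),
            "neuro_disorder": (rng.random(n) < 0.004).astype(int),
            "time_all_cause": time,
            "event_all_cause": event,
            "time_cardiac": time_cardiac,
            "event_cardiac": event_cardiac,
        }
    )
    meta = pd.DataFrame(
        {
            "record_id": ids,
            "has_pacemaker": (rng.random(n) < p.pacemaker_rate).astype(int),
            "af_fraction": np.where(
                rng.random(n) < p.af_excluded_rate, rng.uniform(0.5, 1.0, n), 0.0
            ),
            "heart_transplant": (rng.random(n) < p.transplant_rate).astype(int),
            "wearing_time_h": rng.normal(22.49, 2.0, size=n).clip(6.0),
        }
    )

    markers_df = None
    records: dict[str, RRSeries] = {}
    if p.record_mode == "markers":
        markers_df = pd.DataFrame(marker_vals, columns=marker_names)
        markers_df.insert(0, "record_id", ids)
    else:
        seeds = rng.integers(0, 2**31 - 1, size=n)
        for i, rid in enumerate(ids):
            base = p.rr_healthy if healthy[i] else p.rr_hf
            subj = _jitter_rr_params(base, rng, int(seeds[i]))
            records[rid] = gen_rr_record(subj, record_id=rid)

    truth = {
        "seed": p.seed,
        "n_subjects": n,
        "record_mode": p.record_mode,
        "healthy_fraction": p.healthy_fraction,
        "marker_dists": {m: list(map(list, v)) for m, v in p.marker_dists.items()},
        "log_hr_per_sd": dict(p.log_hr_per_sd),
        "weibull": {"shape": p.weibull_shape, "scale": p.weibull_scale},
        "censor_years": p.censor_years,
        "groups": np.where(healthy, "healthy", "heart_failure").tolist(),
        "marker_z": {m: marker_z[:, j].tolist() for j, m in enumerate(marker_names)},
    }
    return CohortBundle(covariates, markers_df, records, meta, truth)
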