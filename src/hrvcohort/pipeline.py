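"""Configuration-driven end-to-end orchestration.

One declarative config drives the whole analysis path: eligibility ->
artifact filtering -> 20-marker table -> reference ranges and distribution
summary -> dual-track marker selection -> tertile cumulative-incidence
curves -> linear and Cox model batteries. Every artifact is written as CSV
or JSON together with run metadata (effective config, config hash, seed);
the marker table is the single interchange artifact between the
signal-processing and statistics halves, with missing markers carried as
explicit empty cells plus reason codes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import frequency, nonlinear, reference, selection, survival, timedomain
from .preprocess import (
    FilterParams,
    NNSeries,
    RecordMeta,
    check_eligibility,
    filter_to_nn,
    read_rr_text,
    resample_tachogram,
)

logger = logging.getLogger("hrvcohort")

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "MARKER_COLUMNS",
    "compute_record_markers",
    "compute_marker_table",
    "run_pipeline",
]

#: The 20 marker columns of the interchange table, by domain.
MARKER_COLUMNS = [
    # time domain
    "mean_hr", "sdnn", "sdann", "rmssd", "pnn50",
    # frequency domain
    "ulf", "vlf", "lf", "hf", "lf_hf", "total_power", "ulf_fourier", "ulf_wavelet",
    # non-linear indices
    "ac", "dc", "time_lag", "embedding_dim", "fractal_dim",
    "sample_entropy", "max_lyapunov",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage (and record)."""


@dataclass
class PipelineConfig:
    rr_dir: str | None = None
    meta: str | None = None
    covariates: str | None = None
    literature: str | None = None
    out: str = "hrv_out"
    filter: dict = field(default_factory=dict)  # FilterParams fields
    frequency: dict = field(default_factory=dict)  # resample_rate, window_s, shift_s, wavelet
    nonlinear: dict = field(default_factory=dict)  # NonlinearParams fields
    reference: dict = field(default_factory=dict)  # lower_p, upper_p, min_reference_n
    adjustment_full: list = field(
        default_factory=lambda: ["age", "sex", "hypertension", "diabetes",
                                 "dyslipidemia", "smoking", "obesity", "cad", "ckd"]
    )
    selection_top_k: int = 10
    selection_outcome: str = "cardiac"  # outcome driving the survival forest
    forest: dict = field(default_factory=dict)  # ForestParams fields
    outcomes: list = field(default_factory=lambda: ["all_cause", "cardiac"])
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def filter_params(self) -> FilterParams:
        kw = dict(self.filter)
        if "abs_bounds" in kw:
            kw["abs_bounds"] = tuple(kw["abs_bounds"])
        return FilterParams(**kw)

    def nonlinear_params(self) -> nonlinear.NonlinearParams:
        kw = dict(self.nonlinear)
        if "lyap_fit_range" in kw:
            kw["lyap_fit_range"] = tuple(kw["lyap_fit_range"])
        return nonlinear.NonlinearParams(**kw)

    def forest_params(self) -> selection.ForestParams:
        kw = dict(self.forest)
        kw.setdefault("seed", self.seed)
        return selection.ForestParams(**kw)


def compute_record_markers(
    nn: NNSeries, config: PipelineConfig | None = None
) -> tuple[dict[str, float | None], dict[str, str]]:
    """All 20 markers for one NN series; returns (values, missing reasons)."""
    config = config or PipelineConfig()
    values: dict[str, float | None] = {}
    reasons: dict[str, str] = {}
    try:
        values.update(
            timedomain.time_domain_markers(nn).as_dict()
        )
        if values["sdann"] is None:
            reasons["sdann"] = "fewer_than_2_segments"
    except Exception as exc:
        for c in ("mean_hr", "sdnn", "sdann", "rmssd", "pnn50"):
            values[c] = None
            reasons[c] = str(exc)
    fcfg = config.frequency
    try:
        # cubic spline resampling avoids the sinc^2 attenuation linear
        # interpolation applies to the HF band at typical beat rates
        tg = resample_tachogram(
            nn, rate=fcfg.get("resample_rate", 4.0),
            method=fcfg.get("resample_method", "cubic"),
        )
        fvals = frequency.frequency_markers(
            tg,
            stft_window_s=fcfg.get("window_s", 1800.0),
            stft_shift_s=fcfg.get("shift_s", 300.0),
            wavelet=fcfg.get("wavelet", "sym8"),
        )
        values.update(fvals)
        for k, v in fvals.items():
            if v is None:
                reasons[k] = "band_unresolved"
    except Exception as exc:
        for c in ("ulf", "vlf", "lf", "hf", "lf_hf", "total_power",
                  "ulf_fourier", "ulf_wavelet"):
            values[c] = None
            reasons[c] = str(exc)
    nl_vals, nl_reasons = nonlinear.nonlinear_markers(nn, config.nonlinear_params())
    values.update(nl_vals)
    reasons.update(nl_reasons)
    return values, reasons


def compute_marker_table(
    nn_records: dict[str, NNSeries], config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, dict[str, dict[str, str]]]:
    """One row of the 20 markers per record, plus missing-reason codes."""
    rows = []
    all_reasons: dict[str, dict[str, str]] = {}
    for rid, nn in nn_records.items():
        values, reasons = compute_record_markers(nn, config)
        rows.append({"record_id": rid, **values})
        if reasons:
            all_reasons[rid] = reasons
    table = pd.DataFrame(rows, columns=["record_id"] + MARKER_COLUMNS)
    return table, all_reasons


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("eligibility")
def _run_eligibility(config: PipelineConfig) -> pd.DataFrame:
    meta = pd.read_csv(config.meta)
    rows = []
    for _, r in meta.iterrows():
        m = RecordMeta(
            record_id=str(r["record_id"]),
            has_pacemaker=bool(r.get("has_pacemaker", False)),
            af_fraction=float(r.get("af_fraction", 0.0)),
            heart_transplant=bool(r.get("heart_transplant", False)),
            wearing_time_h=float(r.get("wearing_time_h", 24.0)),
        )
        decision = check_eligibility(m)
        rows.append(
            {
                "record_id": m.record_id,
                "included": decision.included,
                "reason": decision.reason or "",
            }
        )
        if not decision.included:
            logger.info("excluded %s: %s", m.record_id, decision.reason)
    table = pd.DataFrame(rows)
    if not table["included"].any():
        raise PipelineError("stage 'eligibility' failed: every record excluded")
    return table


@_stage("preprocess")
def _run_preprocess(config: PipelineConfig, eligible_ids) -> dict[str, NNSeries]:
    params = config.filter_params()
    rr_dir = Path(config.rr_dir)
    out: dict[str, NNSeries] = {}
    for rid in eligible_ids:
        path = rr_dir / f"{rid}.txt"
        if not path.exists():
            logger.warning("no RR file for %s; skipped", rid)
            continue
        rr = read_rr_text(path, record_id=rid)
        nn = filter_to_nn(rr, params)
        logger.info("%s: %d beats accepted, %d rejected", rid, len(nn), nn.rejected_count)
        out[rid] = nn
    if not out:
        raise PipelineError("stage 'preprocess' failed: no RR recordings found")
    return out


@_stage("reference_ranges")
def _run_reference(
    markers: pd.DataFrame, covariates: pd.DataFrame, config: PipelineConfig
):
    rcfg = config.reference
    merged = markers.merge(covariates, on="record_id", how="inner")
    healthy = reference.healthy_mask(merged)
    ranges = {}
    summary_rows = []
    for marker in MARKER_COLUMNS:
        try:
            rng = reference.derive_reference_range(
                merged, healthy, marker,
                lower_p=rcfg.get("lower_p", 0.05),
                upper_p=rcfg.get("upper_p", 0.95),
                min_reference_n=rcfg.get("min_reference_n", 20),
            )
        except ValueError as exc:
            logger.warning("no reference range for %s: %s", marker, exc)
            continue
        ranges[marker] = rng
        hf_vals = pd.to_numeric(
            merged.loc[~healthy, marker], errors="coerce"
        ).dropna()
        ref_vals = pd.to_numeric(
            merged.loc[healthy, marker], errors="coerce"
        ).dropna()
        row = {"marker": marker, "lower": rng.lower, "upper": rng.upper,
               "n_reference": rng.n_reference,
               "convention": reference.QUANTILE_CONVENTION}
        for prefix, vals in (("ref", ref_vals), ("hf", hf_vals)):
            if len(vals):
                s = reference.distribution_summary(vals, rng)
                row.update({f"{prefix}_{k}": v for k, v in s.items()})
        summary_rows.append(row)
    return ranges, pd.DataFrame(summary_rows), healthy, merged


@_stage("selection")
def _run_selection(
    markers: pd.DataFrame, covariates: pd.DataFrame, config: PipelineConfig
):
    lit = pd.read_csv(config.literature)
    lit_ranking = selection.rank_by_hits(lit)
    merged = markers.merge(covariates, on="record_id", how="inner")
    time_col = f"time_{config.selection_outcome}"
    event_col = f"event_{config.selection_outcome}"
    marker_cols = [c for c in MARKER_COLUMNS if c in markers.columns]
    # drop markers missing for most records before the complete-case cut
    marker_cols = [
        c for c in marker_cols
        if pd.to_numeric(merged[c], errors="coerce").notna().mean() >= 0.5
    ]
    feat_cols = marker_cols + ["age", "sex"]
    frame = merged[feat_cols + [time_col, event_col]].apply(
        pd.to_numeric, errors="coerce"
    )
    frame = frame.dropna()
    res = selection.fit_survival_forest(
        frame[feat_cols], frame[time_col], frame[event_col],
        params=config.forest_params(), forced=("age", "sex"),
    )
    forest_ranking = res.ranking(exclude_forced=True)
    k = min(config.selection_top_k, len(lit_ranking), len(forest_ranking))
    selected = selection.select_top_union(lit_ranking, forest_ranking, k=k)
    return lit_ranking, res, forest_ranking, selected


@_stage("models")
def _run_models(
    markers: pd.DataFrame, covariates: pd.DataFrame, ranges, config: PipelineConfig
):
    merged = markers.merge(covariates, on="record_id", how="inner")
    healthy = reference.healthy_mask(merged)
    hf = merged.loc[~healthy].reset_index(drop=True)
    tiers = [
        survival.AdjustmentSet("age_sex", ("age", "sex")),
        survival.AdjustmentSet("full", tuple(config.adjustment_full)),
    ]
    cox_tables = []
    for outcome in config.outcomes:
        for tier in tiers:
            for predictor in ("continuous", "out_of_range"):
                tbl = survival.run_model_battery(
                    hf[["record_id"] + [c for c in MARKER_COLUMNS if c in hf]],
                    hf, tier, outcome=outcome,
                    predictor=predictor, ranges=ranges,
                )
                cox_tables.append(tbl)
    cox_table = pd.concat(cox_tables, ignore_index=True)

    lin_rows = []
    full = tiers[1]
    for marker in MARKER_COLUMNS:
        if marker not in hf:
            continue
        frame = hf[[marker] + list(full.covariates)].apply(
            pd.to_numeric, errors="coerce"
        ).dropna()
        if len(frame) <= len(full.covariates) + 2:
            continue
        sd = frame[marker].std(ddof=1)
        if not sd > 0:
            continue
        try:
            res = survival.linear_fit(
                frame[marker] / sd, frame[list(full.covariates)]
            )
        except ValueError as exc:
            logger.warning("linear model for %s skipped: %s", marker, exc)
            continue
        summ = res.summary().drop(index="intercept")
        summ.insert(0, "marker", marker)
        summ.insert(1, "covariate", summ.index)
        lin_rows.append(summ.reset_index(drop=True))
    linear_table = (
        pd.concat(lin_rows, ignore_index=True) if lin_rows else pd.DataFrame()
    )
    return cox_table, linear_table, hf


@_stage("curves")
def _run_curves(hf: pd.DataFrame, top_markers: list[str]) -> pd.DataFrame:
    frames = []
    for marker in top_markers:
        vals = pd.to_numeric(hf[marker], errors="coerce")
        ok = vals.notna()
        if ok.sum() < 3:
            continue
        cut = reference.tertile_cutpoints(vals[ok])
        groups = np.asarray(
            [None] * len(vals), dtype=object
        )
        groups[ok.to_numpy()] = reference.assign_tertiles(vals[ok], cut)
        curves = survival.cumulative_incidence(
            hf["time_all_cause"].to_numpy(),
            hf["event_all_cause"].to_numpy(),
            groups,
        )
        for g, df in curves.items():
            df = df.copy()
            df.insert(0, "marker", marker)
            df.insert(1, "tertile", g)
            df["t1"], df["t2"] = cut
            frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of in-memory artifacts.

    Artifacts are also written under ``config.out``:
    eligibility.csv, markers.csv, marker_missing_reasons.json,
    reference_ranges_summary.csv, literature_ranking.csv, forest_ranking.csv,
    selection_report.json, cumulative_incidence.csv, cox_models.csv,
    linear_models.csv, run_metadata.json.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    covariates = pd.read_csv(config.covariates)
    covariates["record_id"] = covariates["record_id"].astype(str)

    eligibility = _run_eligibility(config)
    eligible = eligibility.loc[eligibility["included"], "record_id"].tolist()
    nn_records = _run_preprocess(config, eligible)
    markers, reasons = compute_marker_table(nn_records, config)

    ranges, summary, healthy, merged = _run_reference(markers, covariates, config)
    lit_ranking, forest_res, forest_ranking, selected = _run_selection(
        markers, covariates, config
    )
    cox_table, linear_table, hf = _run_models(markers, covariates, ranges, config)
    curves = _run_curves(hf, forest_ranking[:2])

    eligibility.to_csv(out / "eligibility.csv", index=False)
    markers.to_csv(out / "markers.csv", index=False)
    (out / "marker_missing_reasons.json").write_text(json.dumps(reasons, indent=2))
    summary.to_csv(out / "reference_ranges_summary.csv", index=False)
    pd.DataFrame({"marker": lit_ranking, "rank": range(1, len(lit_ranking) + 1)}).to_csv(
        out / "literature_ranking.csv", index=False
    )
    forest_res.summary().to_csv(out / "forest_ranking.csv", index=False)
    (out / "selection_report.json").write_text(json.dumps(selected, indent=2))
    curves.to_csv(out / "cumulative_incidence.csv", index=False)
    cox_table.to_csv(out / "cox_models.csv", index=False)
    linear_table.to_csv(out / "linear_models.csv", index=False)
    (out / "run_metadata.json").write_text(
        json.dumps(
            {
                "config": config.to_dict(),
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "n_records": len(nn_records),
                "n_reference": int(np.sum(healthy)),
            },
            indent=2,
        )
    )
    return {
        "eligibility": eligibility,
        "markers": markers,
        "missing_reasons": reasons,
        "ranges": ranges,
        "summary": summary,
        "literature_ranking": lit_ranking,
        "forest_ranking": forest_ranking,
        "selected": selected,
        "curves": curves,
        "cox_models": cox_table,
        "linear_models": linear_table,
    }
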