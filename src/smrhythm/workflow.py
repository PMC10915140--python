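"""Pipeline orchestration: simulate -> features -> stats, with config and logging."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bursting import BurstSettings, detect_bursts, mu_beta_envelope, summarize_bursts
from .exceptions import InvalidParameterError, SchemaError, SmrhythmError
from .inference import (
    DEFAULT_ORDER,
    clinical_regression,
    sequential_bf,
    welch_t_test,
    yates_chi_square,
)
from .io import read_recording, write_events, write_report, write_results
from .recording import TimeSeriesRecording
from .spectral import (
    ALPHA_BAND,
    BETA_BAND,
    fit_spectral_model,
    raw_band_peak,
    select_band_peak,
    welch_psd,
)
from .synthgen import FEATURES, SUBSCALES

logger = logging.getLogger("smrhythm")

CONFIG_SCHEMA_VERSION = 1

# Exit codes used by the CLI.
EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


@dataclass
class PipelineConfig:
    """All pipeline settings with their standard default values."""

    schema_version: int = CONFIG_SCHEMA_VERSION
    recordings: dict = field(default_factory=dict)  # subject_id -> path
    subjects_csv: str | None = None  # covariate/clinical table
    welch: dict = field(
        default_factory=lambda: {
            "segment_s": 3.072, "overlap": 0.5, "fmin": 0.5, "fmax": 40.0
        }
    )
    spectral_fit: dict = field(
        default_factory=lambda: {
            "max_peaks": 8,
            "peak_threshold_sd": 2.0,
            "min_peak_height": 0.05,
            "bw_limits": (0.75, 12.0),
        }
    )
    burst: dict = field(
        default_factory=lambda: {
            "band": (8.0, 30.0), "threshold_factor": 2.0, "edge_rule": "half_max"
        }
    )
    model_order: tuple = tuple(DEFAULT_ORDER)
    bf_cutoff: float = 3.0
    seed: int = 0
    output_dir: str = "smrhythm_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        version = raw.get("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise InvalidParameterError(
                f"unsupported config schema version {version}"
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.model_order = tuple(cfg.model_order)
        return cfg

    def settings_used(self) -> dict:
        """A serializable 'settings used' block for the run report."""
        return {
            "schema_version": self.schema_version,
            "welch": dict(self.welch),
            "spectral_fit": {**self.spectral_fit, "bw_limits": list(self.spectral_fit["bw_limits"])},
            "burst": {**self.burst, "band": list(self.burst["band"])},
            "model_order": list(self.model_order),
            "bf_cutoff": self.bf_cutoff,
            "seed": self.seed,
            "version": __version__,
        }


def extract_features(
    recording: TimeSeriesRecording, config: PipelineConfig | None = None
) -> tuple[dict, list]:
    """All ten signal features (plus raw-PSD variants) for one recording.

    Returns the feature dict and the detected burst events.
    """
    config = config or PipelineConfig()
    psd = welch_psd(recording, **config.welch)
    fit = fit_spectral_model(psd, **config.spectral_fit)

    row: dict = {
        "aperiodic_offset": fit.offset,
        "aperiodic_exponent": fit.exponent,
        "r_squared": fit.r_squared,
    }
    for band, prefix in ((ALPHA_BAND, "alpha"), (BETA_BAND, "beta")):
        peak = select_band_peak(fit, band)
        row[f"{prefix}_power"] = peak.height if peak else np.nan
        row[f"{prefix}_cf"] = peak.centre_freq if peak else np.nan
        raw_power, raw_cf = raw_band_peak(psd, band)
        row[f"{prefix}_power_raw"] = raw_power
        row[f"{prefix}_cf_raw"] = raw_cf

    settings = BurstSettings(
        band=tuple(config.burst["band"]),
        threshold_factor=config.burst["threshold_factor"],
        edge_rule=config.burst["edge_rule"],
    )
    envelope = mu_beta_envelope(recording, band=settings.band)
    events = detect_bursts(envelope, settings)
    summary = summarize_bursts(events, analyzed_s=recording.duration_s)
    row.update(
        {
            "burst_rate": summary.rate,
            "burst_duration": summary.median_duration_ms,
            "burst_interval": summary.median_interval_ms,
            "burst_amplitude": summary.median_amplitude,
            "n_events": summary.n_events,
            "analyzed_s": summary.analyzed_s,
        }
    )
    return row, events


def run_features(
    config: PipelineConfig,
    recordings: dict[str, TimeSeriesRecording] | None = None,
) -> pd.DataFrame:
    """Per-subject feature extraction over configured or provided recordings.

    Per-subject failures are logged and recorded; the run continues.  If
    every subject fails, a SmrhythmError is raised (CLI exit code 3).
    """
    if recordings is None:
        recordings = {}
        for sid, path in config.recordings.items():
            try:
                recordings[sid] = read_recording(path, subject_id=sid)
            except Exception as exc:
                logger.error("subject %s: unreadable input (%s)", sid, exc)
                recordings[sid] = None

    rows, events_by_subject, failures = [], {}, []
    for sid, recording in recordings.items():
        if recording is None:
            failures.append(sid)
            continue
        try:
            row, events = extract_features(recording, config)
        except SmrhythmError as exc:
            logger.error("subject %s: feature extraction failed (%s)", sid, exc)
            failures.append(sid)
            continue
        logger.info(
            "subject %s: r_squared=%.3f, %d burst events",
            sid, row["r_squared"], row["n_events"],
        )
        row["subject_id"] = sid
        rows.append(row)
        events_by_subject[sid] = events

    if recordings and not rows:
        raise SmrhythmError("feature extraction failed for every subject")

    columns = [
        "subject_id",
        "alpha_power", "alpha_cf", "beta_power", "beta_cf",
        "alpha_power_raw", "alpha_cf_raw", "beta_power_raw", "beta_cf_raw",
        "aperiodic_offset", "aperiodic_exponent", "r_squared",
        "burst_rate", "burst_duration", "burst_interval", "burst_amplitude",
        "n_events", "analyzed_s",
    ]
    table = pd.DataFrame(rows, columns=columns)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "features.csv", index=False)
    write_events(events_by_subject, outdir / "events.tsv")
    if failures:
        (outdir / "failures.txt").write_text("\n".join(failures) + "\n")
    return table


_STATS_REQUIRED = ["group", "age", "sex", "cortical_thickness"]


def run_stats(features: pd.DataFrame, config: PipelineConfig) -> dict:
    """Both regression analyses plus the demographic tests.

    Returns the JSON-serializable run report (also written to the output
    directory together with a tidy results CSV).
    """
    missing = [c for c in _STATS_REQUIRED if c not in features.columns]
    if missing:
        raise SchemaError(missing)

    report: dict = {"settings": config.settings_used(), "flagged": [], "warnings": []}
    result_rows: list[dict] = []

    # Demographics (group x sex chi-square, Welch t on age).
    grp = features["group"].astype(str)
    if set(grp.unique()) >= {"pd", "hc"}:
        sex_tab = [
            [
                int(((grp == g) & (features["sex"] == "female")).sum()),
                int(((grp == g) & (features["sex"] == "male")).sum()),
            ]
            for g in ("pd", "hc")
        ]
        try:
            chi2, p_chi = yates_chi_square(sex_tab)
            ages = {g: features.loc[grp == g, "age"] for g in ("pd", "hc")}
            t, df, p_t = welch_t_test(
                ages["pd"].mean(), ages["pd"].std(ddof=1), len(ages["pd"]),
                ages["hc"].mean(), ages["hc"].std(ddof=1), len(ages["hc"]),
            )
            report["demographics"] = {
                "sex_table": sex_tab,
                "sex_chi2": chi2, "sex_p": p_chi,
                "age_t": t, "age_df": df, "age_p": p_t,
            }
        except SmrhythmError as exc:
            report["warnings"].append(f"demographics skipped: {exc}")

    # Analysis 1: feature ~ group/age/age2/sex/thickness (+ interactions).
    analysis1 = {}
    for outcome in FEATURES:
        if outcome not in features.columns:
            continue
        try:
            result = sequential_bf(features, outcome, order=config.model_order)
        except SmrhythmError as exc:
            report["warnings"].append(f"{outcome}: {exc}")
            continue
        analysis1[outcome] = {
            name: {"estimate": s.estimate, "ci_low": s.ci_low,
                   "ci_high": s.ci_high, "bf10": s.bf10}
            for name, s in result.stats.items()
        }
        for name, s in result.stats.items():
            result_rows.append(
                {"outcome": outcome, "family": result.family, "predictor": name,
                 "estimate": s.estimate, "ci_low": s.ci_low,
                 "ci_high": s.ci_high, "bf10": s.bf10}
            )
            if s.bf10 > config.bf_cutoff:
                report["flagged"].append({"outcome": outcome, "predictor": name,
                                          "bf10": s.bf10})
    report["analysis1"] = analysis1

    # Analysis 2: PD clinical subscales ~ signal features + covariates.
    subscale_cols = [s for s in SUBSCALES if s in features.columns]
    clinical_ready = subscale_cols and all(
        c in features.columns for c in ("disease_duration", "ledd")
    )
    analysis2 = {}
    if not clinical_ready:
        msg = "clinical columns missing; analysis 2 skipped"
        logger.warning(msg)
        report["warnings"].append(msg)
    else:
        for symptom in subscale_cols:
            try:
                result = clinical_regression(features, symptom)
            except SmrhythmError as exc:
                report["warnings"].append(f"{symptom}: {exc}")
                continue
            analysis2[symptom] = {
                name: {"estimate": s.estimate, "ci_low": s.ci_low,
                       "ci_high": s.ci_high, "bf10": s.bf10}
                for name, s in result.stats.items()
            }
            for name, s in result.stats.items():
                result_rows.append(
                    {"outcome": symptom, "family": result.family, "predictor": name,
                     "estimate": s.estimate, "ci_low": s.ci_low,
                     "ci_high": s.ci_high, "bf10": s.bf10}
                )
                if s.bf10 > config.bf_cutoff:
                    report["flagged"].append({"outcome": symptom, "predictor": name,
                                              "bf10": s.bf10})
    report["analysis2"] = analysis2

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_results(result_rows, outdir / "results.csv")
    write_report(report, outdir / "report.json")
    return report
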