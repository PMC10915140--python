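"""Synthetic signals and cohorts with known ground truth.

Everything downstream (spectral parameterization, burst detection, the two
regression analyses) is exercised against outputs of this module, so the
generative models here are deliberately exact twins of what the analysis
assumes: a power-law PSD with optional log-Gaussian oscillatory peaks,
Hann-windowed sinusoidal bursts placed by a Poisson process, and cohorts
whose features follow Gaussian linear / Poisson log-linear models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert as _hilbert
from scipy.stats import truncnorm

from .exceptions import InfeasiblePlacementError, InvalidParameterError
from .recording import TimeSeriesRecording

__all__ = [
    "SignalParams",
    "CohortParams",
    "generate_aperiodic_signal",
    "generate_burst_train",
    "generate_cohort",
    "generation_design",
    "FEATURES",
    "GAUSSIAN_FEATURES",
    "COUNT_FEATURES",
    "SUBSCALES",
    "MAIN_PREDICTORS",
    "INTERACTION_PREDICTORS",
    "CLINICAL_COVARIATES",
]

# The ten signal features extracted per subject, in canonical order.
FEATURES = (
    "alpha_power",
    "alpha_cf",
    "beta_power",
    "beta_cf",
    "aperiodic_offset",
    "aperiodic_exponent",
    "burst_rate",
    "burst_duration",
    "burst_interval",
    "burst_amplitude",
)
COUNT_FEATURES = ("burst_rate",)
GAUSSIAN_FEATURES = tuple(f for f in FEATURES if f not in COUNT_FEATURES)

SUBSCALES = (
    "midline_function",
    "rest_tremor",
    "rigidity",
    "upper_bradykinesia_contra",
    "upper_bradykinesia_ipsi",
    "postural_kinetic_tremor",
    "lower_limb_bradykinesia",
    "updrs3_total",
)

MAIN_PREDICTORS = ("group", "age", "age2", "sex", "thickness")
# Two-way interactions among the four base predictors, lexical order.
INTERACTION_PREDICTORS = (
    "age:group",
    "age:sex",
    "age:thickness",
    "group:sex",
    "group:thickness",
    "sex:thickness",
)
CLINICAL_COVARIATES = ("age", "sex", "disease_duration", "ledd", "thickness")

_AGE_TRUNC = (44.0, 85.0)  # recruitment span, years


@dataclass(frozen=True)
class SignalParams:
    """Ground-truth parameters for a single synthetic recording.

    ``oscillations`` entries are ``(centre_freq_hz, log10_height,
    bandwidth_hz)`` added to the log10 PSD as Gaussians (bandwidth = 2 sigma).
    Burst parameters describe a Poisson event train of Hann-windowed
    sinusoids superposed on the (optional) aperiodic background.
    """

    duration_s: float = 180.0
    fs: float = 1000.0
    aperiodic_offset: float = -20.0
    aperiodic_exponent: float = 1.5
    oscillations: tuple[tuple[float, float, float], ...] = ()
    burst_rate: float = 0.0  # events per minute
    burst_duration_mean_ms: float = 100.0
    burst_duration_sd_ms: float = 30.0
    burst_amplitude: float = 1.0
    burst_centre_freq: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not (self.duration_s > 0):
            raise InvalidParameterError("duration_s must be positive")
        if not (self.fs > 0):
            raise InvalidParameterError("fs must be positive")
        fmax = max((c for c, _, _ in self.oscillations), default=0.0)
        fmax = max(fmax, self.burst_centre_freq if self.burst_rate > 0 else 0.0)
        if fmax > 0 and self.fs <= 2 * fmax:
            raise InvalidParameterError(
                f"fs={self.fs} must exceed twice the highest oscillation "
                f"frequency ({fmax} Hz)"
            )
        if self.burst_rate < 0:
            raise InvalidParameterError("burst_rate must be non-negative")
        if not (self.burst_duration_mean_ms > 0):
            raise InvalidParameterError("burst_duration_mean_ms must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _target_log10_psd(params: SignalParams, freqs: np.ndarray) -> np.ndarray:
    """Target one-sided log10 PSD at strictly positive frequencies."""
    logp = params.aperiodic_offset - params.aperiodic_exponent * np.log10(freqs)
    for centre, height, bandwidth in params.oscillations:
        sigma = bandwidth / 2.0
        logp = logp + height * np.exp(-((freqs - centre) ** 2) / (2 * sigma**2))
    return logp


def generate_aperiodic_signal(params: SignalParams) -> TimeSeriesRecording:
    """Spectrally shaped noise with an exact expected power-law PSD.

    Shaping is done in the frequency domain: deterministic amplitudes
    proportional to sqrt(target PSD) with uniformly random phases, DC and
    Nyquist bins zeroed.  The one-sided Welch PSD of the output obeys
    ``log10 P(f) = offset - exponent * log10 f`` (plus any oscillation
    Gaussians) in expectation.
    """
    n = params.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / params.fs)
    rng = np.random.default_rng(params.seed)

    psd = np.zeros_like(freqs)
    psd[1:] = 10.0 ** _target_log10_psd(params, freqs[1:])
    # One-sided density P relates to rFFT coefficients by |X_k|^2 = P * fs * n / 2.
    amplitude = np.sqrt(psd * params.fs * n / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    spectrum = amplitude * np.exp(1j * phases)
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = 0.0
    samples = np.fft.irfft(spectrum, n)
    return TimeSeriesRecording(samples=samples, fs=params.fs, truth_events=[])


def _truncated_durations(rng, n, mean_ms, sd_ms):
    """Burst durations in seconds: normal truncated at +/-2 SD and at 20 ms."""
    lo = max(20.0, mean_ms - 2.0 * sd_ms)
    hi = max(lo + 1e-9, mean_ms + 2.0 * sd_ms)
    if sd_ms <= 0:
        return np.full(n, mean_ms / 1000.0)
    a, b = (lo - mean_ms) / sd_ms, (hi - mean_ms) / sd_ms
    dist = truncnorm(a, b, loc=mean_ms, scale=sd_ms)
    return dist.rvs(size=n, random_state=rng) / 1000.0


_MAX_PLACEMENT_ATTEMPTS = 10_000


def generate_burst_train(
    params: SignalParams,
    *,
    n_events: int | None = None,
    include_background: bool = False,
    min_gap_s: float = 0.2,
    edge_margin_s: float = 0.5,
) -> TimeSeriesRecording:
    """Poisson train of Hann-windowed sinusoidal bursts.

    Each burst is ``amplitude * hann(t) * sin(2 pi f t + phi)`` so its
    analytic envelope peaks at exactly ``burst_amplitude``.  Placement is
    non-overlapping by rejection sampling (with ``min_gap_s`` guard so the
    band-pass filter of the detector cannot smear neighbours together) and
    keeps ``edge_margin_s`` clear of the recording edges.  ``truth_events``
    records ``(onset_s, offset_s, peak_amplitude)`` per burst.

    ``n_events`` overrides the Poisson draw with an exact count (used by
    count-recovery tests); ``include_background`` superposes the aperiodic
    background defined by the same params.
    """
    rng = np.random.default_rng(params.seed)
    duration = params.duration_s
    n = params.n_samples

    if n_events is None:
        count = int(rng.poisson(params.burst_rate * duration / 60.0))
    else:
        count = int(n_events)

    mean_dur_s = params.burst_duration_mean_ms / 1000.0
    expected_rate = (count / (duration / 60.0)) if n_events is not None else params.burst_rate
    if expected_rate / 60.0 * duration * mean_dur_s > 0.8 * duration:
        raise InfeasiblePlacementError(
            "requested burst load exceeds 80% of the recording duration"
        )

    if include_background:
        background = generate_aperiodic_signal(params)
        samples = background.samples.copy()
    else:
        samples = np.zeros(n)

    durations = _truncated_durations(
        rng, count, params.burst_duration_mean_ms, params.burst_duration_sd_ms
    )
    placed: list[tuple[float, float]] = []
    truth: list[tuple[float, float, float]] = []
    for d in durations:
        lo, hi = edge_margin_s, duration - edge_margin_s - d
        if hi <= lo:
            raise InfeasiblePlacementError("burst longer than usable recording span")
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            onset = rng.uniform(lo, hi)
            offset = onset + d
            if all(
                offset + min_gap_s <= s or onset >= e + min_gap_s for s, e in placed
            ):
                placed.append((onset, offset))
                break
        else:
            raise InfeasiblePlacementError(
                f"could not place {count} non-overlapping bursts in "
                f"{duration:g} s after {_MAX_PLACEMENT_ATTEMPTS} attempts"
            )
        i0 = int(round(onset * params.fs))
        i1 = int(round(offset * params.fs))
        t = np.arange(i1 - i0) / params.fs
        window = np.hanning(i1 - i0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        burst = window * np.sin(2.0 * np.pi * params.burst_centre_freq * t + phase)
        # Short bursts are only a few cycles, so the analytic envelope of a
        # windowed tone undershoots the window; rescale so the realized
        # envelope peak equals the specified amplitude exactly.
        padded = np.concatenate([np.zeros(burst.size), burst, np.zeros(burst.size)])
        analytic_peak = np.abs(_hilbert(padded)).max()
        burst *= params.burst_amplitude / analytic_peak
        samples[i0:i1] += burst
        truth.append((onset, offset, params.burst_amplitude))

    truth.sort()
    return TimeSeriesRecording(samples=samples, fs=params.fs, truth_events=truth)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

_DEFAULT_INTERCEPTS = {
    "alpha_power": 0.35,
    "alpha_cf": 10.0,
    "beta_power": 0.30,
    "beta_cf": 20.0,
    "aperiodic_offset": -20.5,
    "aperiodic_exponent": 1.2,
    "burst_rate": np.log(80.0),  # log events/minute
    "burst_duration": np.log(120.0),  # log ms
    "burst_interval": np.log(500.0),  # log ms
    "burst_amplitude": np.log(3.0e-11),  # log envelope units
}


@dataclass(frozen=True)
class CohortParams:
    """Parameters of a synthetic cohort with configurable effect structure.

    ``feature_effects[feature][predictor]`` gives the true coefficient of a
    generation-design predictor (see :func:`generation_design`) on that
    feature — on the Gaussian outcome scale, or the log-rate scale for the
    burst count.  ``clinical_effects[subscale][key]`` gives effects of
    z-scored features (or covariates) on PD symptom subscales.
    """

    n_pd: int = 78
    n_hc: int = 60
    age_mean_pd: float = 65.6
    age_sd_pd: float = 9.5
    age_mean_hc: float = 63.93
    age_sd_hc: float = 8.4
    female_ratio_pd: float = 29 / 78
    female_ratio_hc: float = 27 / 60
    thickness_mean: float = 2.5
    thickness_sd: float = 0.15
    feature_effects: dict = field(default_factory=dict)
    noise_sd: dict | float = 1.0
    intercepts: dict = field(default_factory=dict)
    clinical_effects: dict = field(default_factory=dict)
    clinical_noise_sd: float = 1.0
    recording_minutes: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pd < 2 or self.n_hc < 2:
            raise InvalidParameterError("n_pd and n_hc must each be >= 2")
        sds = (
            self.noise_sd.values() if isinstance(self.noise_sd, dict) else [self.noise_sd]
        )
        if any(s < 0 for s in sds):
            raise InvalidParameterError("noise_sd must be non-negative")
        valid = set(MAIN_PREDICTORS) | set(INTERACTION_PREDICTORS)
        for feature, effects in self.feature_effects.items():
            if feature not in FEATURES:
                raise InvalidParameterError(f"unknown feature '{feature}'")
            for key in effects:
                if key not in valid:
                    raise InvalidParameterError(f"unknown predictor key '{key}'")
        valid_clin = set(FEATURES) | set(CLINICAL_COVARIATES)
        for subscale, effects in self.clinical_effects.items():
            if subscale not in SUBSCALES:
                raise InvalidParameterError(f"unknown subscale '{subscale}'")
            for key in effects:
                if key not in valid_clin:
                    raise InvalidParameterError(f"unknown clinical key '{key}'")


def generation_design(table: pd.DataFrame) -> pd.DataFrame:
    """Design matrix on the scale the cohort generator plants effects on.

    Columns: ``group``/``sex`` as 0/1 (hc/pd, female/male), ``age`` centred
    at the sample mean (years), ``age2`` the square of centred age,
    ``thickness`` centred (mm), and the six pairwise interaction products.
    Centring is at sample means so noiseless OLS on this matrix returns the
    planted coefficients exactly.
    """
    group = (
        table["group"].map({"hc": 0.0, "pd": 1.0})
        if table["group"].dtype == object
        else table["group"].astype(float)
    )
    sex = (
        table["sex"].map({"female": 0.0, "male": 1.0})
        if table["sex"].dtype == object
        else table["sex"].astype(float)
    )
    age_c = table["age"] - table["age"].mean()
    thick_c = table["cortical_thickness"] - table["cortical_thickness"].mean()
    design = pd.DataFrame(
        {
            "group": group,
            "age": age_c,
            "age2": age_c**2,
            "sex": sex,
            "thickness": thick_c,
        },
        index=table.index,
    )
    base = {"age": design["age"], "group": group, "sex": sex, "thickness": design["thickness"]}
    for key in INTERACTION_PREDICTORS:
        a, b = key.split(":")
        design[key] = base[a] * base[b]
    return design


def _truncated_normal(rng, n, mean, sd, lo, hi):
    if sd <= 0:
        return np.full(n, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm(a, b, loc=mean, scale=sd).rvs(size=n, random_state=rng)


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """One row per subject: covariates, clinical subscales, signal features.

    Gaussian features follow ``intercept + X beta + N(0, noise_sd)`` on the
    generation design; the burst count follows a Poisson log-linear model
    with exposure = recording minutes (``burst_rate`` is the realized
    count / minutes).  PD clinical subscales follow
    ``intercept + sum(effect * z(feature)) + N(0, clinical_noise_sd)``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_pd + params.n_hc

    group = np.array(["pd"] * params.n_pd + ["hc"] * params.n_hc)
    age = np.concatenate(
        [
            _truncated_normal(
                rng, params.n_pd, params.age_mean_pd, params.age_sd_pd, *_AGE_TRUNC
            ),
            _truncated_normal(
                rng, params.n_hc, params.age_mean_hc, params.age_sd_hc, *_AGE_TRUNC
            ),
        ]
    )
    sex = np.concatenate(
        [
            np.where(rng.random(params.n_pd) < params.female_ratio_pd, "female", "male"),
            np.where(rng.random(params.n_hc) < params.female_ratio_hc, "female", "male"),
        ]
    )
    thickness = rng.normal(params.thickness_mean, params.thickness_sd, n)

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "group": group,
            "age": age,
            "sex": sex,
            "cortical_thickness": thickness,
        }
    )
    is_pd = table["group"] == "pd"
    table["disease_duration"] = np.where(
        is_pd, _truncated_normal(rng, n, 4.4, 3.7, 0.1, 25.0), np.nan
    )
    table["ledd"] = np.where(is_pd, np.clip(rng.normal(548.0, 273.0, n), 0.0, None), np.nan)
    table["moca"] = np.clip(rng.normal(26.1, 2.5, n), 0.0, 30.0)

    design = generation_design(table)
    intercepts = {**_DEFAULT_INTERCEPTS, **params.intercepts}

    def noise_sd_for(feature):
        if isinstance(params.noise_sd, dict):
            return params.noise_sd.get(feature, 0.0)
        return params.noise_sd

    minutes = params.recording_minutes
    table["analyzed_s"] = minutes * 60.0
    for feature in FEATURES:
        effects = params.feature_effects.get(feature, {})
        linpred = np.full(n, float(intercepts[feature]))
        for key, beta in effects.items():
            linpred = linpred + beta * design[key].to_numpy()
        if feature in COUNT_FEATURES:
            lam = np.exp(linpred) * minutes
            counts = rng.poisson(lam).astype(float)
            table["n_events"] = counts
            table[feature] = counts / minutes
        else:
            values = linpred + rng.normal(0.0, noise_sd_for(feature), n)
            if feature in ("burst_duration", "burst_interval", "burst_amplitude"):
                values = np.exp(values)  # stored on the natural scale, log-linear model
            table[feature] = values

    # Clinical subscales: PD rows only, effects on z-scored features/covariates.
    pd_rows = table.index[is_pd]
    for subscale in SUBSCALES:
        effects = params.clinical_effects.get(subscale, {})
        y = np.full(len(pd_rows), 0.0)
        for key, beta in effects.items():
            if key == "sex":
                x = (table.loc[pd_rows, "sex"] == "male").astype(float).to_numpy()
            elif key == "age":
                x = table.loc[pd_rows, "age"].to_numpy()
                x = x - x.mean()
            else:
                col = "cortical_thickness" if key == "thickness" else key
                x = table.loc[pd_rows, col].to_numpy(dtype=float)
                sd = x.std(ddof=0)
                x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
            y = y + beta * x
        y = y + rng.normal(0.0, params.clinical_noise_sd, len(pd_rows))
        table[subscale] = np.nan
        table.loc[pd_rows, subscale] = y

    return table
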