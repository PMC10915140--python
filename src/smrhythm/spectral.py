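"""PSD estimation and aperiodic + periodic spectral parameterization.

The decomposition follows the standard iterative scheme for neural power
spectra: a log-linear aperiodic fit is subtracted, Gaussian peaks are
extracted iteratively from the flattened spectrum and jointly refined, and
the aperiodic component is refit on the peak-removed spectrum.  All fitting
is done on log10 power with a fixed (no-knee) aperiodic form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

from .exceptions import (
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
)
from .recording import TimeSeriesRecording

__all__ = [
    "PowerSpectrum",
    "SpectralPeak",
    "SpectralFit",
    "welch_psd",
    "fit_spectral_model",
    "select_band_peak",
    "raw_band_peak",
    "ALPHA_BAND",
    "BETA_BAND",
]

ALPHA_BAND = (8.0, 12.0)
BETA_BAND = (13.0, 30.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PowerSpectrum:
    """One-sided PSD restricted to the fitting range."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise InvalidParameterError("freqs and power must be 1-D and equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise InvalidParameterError("freqs must be strictly increasing")

    def band_slice(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return (self.freqs >= lo) & (self.freqs <= hi)


@dataclass(frozen=True)
class SpectralPeak:
    """Gaussian peak above the aperiodic curve.

    ``height`` is in log10-power units; ``bandwidth`` is 2 sigma in Hz.
    """

    centre_freq: float
    height: float
    bandwidth: float

    @property
    def sigma(self) -> float:
        return self.bandwidth / 2.0


@dataclass
class SpectralFit:
    """Aperiodic parameters, fitted peaks and goodness of fit."""

    offset: float
    exponent: float
    peaks: list[SpectralPeak]
    r_squared: float
    alpha_peak: SpectralPeak | None = None
    beta_peak: SpectralPeak | None = None
    settings: dict = field(default_factory=dict)

    def model(self, freqs: np.ndarray) -> np.ndarray:
        """Modelled log10 power at the given frequencies."""
        freqs = np.asarray(freqs, dtype=float)
        out = self.offset - self.exponent * np.log10(freqs)
        for p in self.peaks:
            out = out + p.height * np.exp(
                -((freqs - p.centre_freq) ** 2) / (2 * p.sigma**2)
            )
        return out


def welch_psd(
    recording: TimeSeriesRecording,
    segment_s: float = 3.072,
    overlap: float = 0.5,
    fmin: float = 0.5,
    fmax: float = 40.0,
) -> PowerSpectrum:
    """Welch PSD with Hann-tapered, mean-averaged overlapping segments.

    Frequency resolution is ``1/segment_s``; the spectrum is trimmed to
    ``[fmin, fmax]``.
    """
    if not (0 <= overlap < 1):
        raise InvalidParameterError("overlap must be in [0, 1)")
    nperseg = int(round(segment_s * recording.fs))
    if recording.n_samples < nperseg:
        raise InsufficientDataError(
            f"recording of {recording.duration_s:.3f} s is shorter than one "
            f"{segment_s:g} s segment"
        )
    freqs, power = sps.welch(
        recording.samples,
        fs=recording.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend="constant",
        average="mean",
        scaling="density",
    )
    keep = (freqs >= fmin) & (freqs <= fmax)
    return PowerSpectrum(freqs=freqs[keep], power=power[keep])


def _linfit_log(log_freqs: np.ndarray, log_power: np.ndarray) -> tuple[float, float]:
    """Least-squares (offset, exponent) of log10 power on log10 frequency."""
    slope, intercept = np.polyfit(log_freqs, log_power, 1)
    return float(intercept), float(-slope)


def _robust_aperiodic(
    log_freqs: np.ndarray, log_power: np.ndarray
) -> tuple[float, float]:
    """Initial fit, then refit excluding bins sitting on top of peaks.

    Positive residuals are clamped at zero and bins above the 2.5th
    percentile of the clamped residuals are dropped, so only bins at or
    below the aperiodic trend survive into the refit.
    """
    offset, exponent = _linfit_log(log_freqs, log_power)
    resid = log_power - (offset - exponent * log_freqs)
    flat = np.clip(resid, 0.0, None)
    thresh = np.percentile(flat, 2.5)
    mask = flat <= thresh
    if mask.sum() >= 2:
        offset, exponent = _linfit_log(log_freqs[mask], log_power[mask])
    return offset, exponent


def _guess_sigma(freqs, flat, idx, height, bw_limits):
    """Half-height width estimate for the peak at ``idx``, clamped to bounds."""
    half = height / 2.0
    left = idx
    while left > 0 and flat[left - 1] > half:
        left -= 1
    right = idx
    while right < flat.size - 1 and flat[right + 1] > half:
        right += 1
    # One-sided widths guard against shoulders on overlapping peaks.
    widths = []
    if left > 0:
        widths.append(freqs[idx] - freqs[left])
    if right < flat.size - 1:
        widths.append(freqs[right] - freqs[idx])
    fwhm = 2.0 * min(widths) if widths else bw_limits[0]
    sigma = fwhm * _FWHM_TO_SIGMA
    return float(np.clip(sigma, bw_limits[0] / 2.0, bw_limits[1] / 2.0))


def _multi_gaussian(freqs, *params):
    out = np.zeros_like(freqs)
    for i in range(0, len(params), 3):
        c, h, s = params[i : i + 3]
        out = out + h * np.exp(-((freqs - c) ** 2) / (2 * s**2))
    return out


def fit_spectral_model(
    psd: PowerSpectrum,
    max_peaks: int = 8,
    peak_threshold_sd: float = 2.0,
    min_peak_height: float = 0.05,
    bw_limits: tuple[float, float] = (0.75, 12.0),
) -> SpectralFit:
    """Decompose a PSD into aperiodic offset/exponent plus Gaussian peaks.

    Raises
    ------
    InvalidParameterError
        If the PSD contains non-finite or non-positive power.
    FitFailureError
        If the joint Gaussian refinement fails to converge; the partial
        result (aperiodic fit with the unrefined peak guesses) is attached.
    """
    if psd.freqs.size < 20:
        raise InsufficientDataError("need at least 20 frequency bins to fit")
    if not np.all(np.isfinite(psd.power)) or np.any(psd.power <= 0):
        raise InvalidParameterError("PSD power must be finite and positive")

    freqs = psd.freqs
    log_freqs = np.log10(freqs)
    log_power = np.log10(psd.power)
    fmin, fmax = float(freqs[0]), float(freqs[-1])

    # (1)-(2) robust aperiodic fit, (3) flatten.
    offset, exponent = _robust_aperiodic(log_freqs, log_power)
    flat = log_power - (offset - exponent * log_freqs)

    # (4) iterative peak extraction from the flattened spectrum.
    guesses: list[tuple[float, float, float]] = []
    work = flat.copy()
    for _ in range(max_peaks):
        idx = int(np.argmax(work))
        height = float(work[idx])
        stop = max(peak_threshold_sd * float(np.std(work)), min_peak_height)
        if height < stop:
            break
        centre = float(freqs[idx])
        sigma = _guess_sigma(freqs, work, idx, height, bw_limits)
        guesses.append((centre, height, sigma))
        work = work - height * np.exp(-((freqs - centre) ** 2) / (2 * sigma**2))

    # (5) joint refinement of all Gaussians on the flattened spectrum.
    peaks: list[SpectralPeak] = []
    if guesses:
        p0 = np.array(guesses).ravel()
        lo_b, hi_b = [], []
        for centre, height, sigma in guesses:
            lo_b += [fmin, 0.0, bw_limits[0] / 2.0]
            hi_b += [fmax, np.inf, bw_limits[1] / 2.0]
        try:
            popt, _ = curve_fit(
                _multi_gaussian, freqs, flat, p0=p0, bounds=(lo_b, hi_b), maxfev=8000
            )
        except (RuntimeError, ValueError) as exc:
            partial = SpectralFit(
                offset=offset,
                exponent=exponent,
                peaks=[SpectralPeak(c, h, 2 * s) for c, h, s in guesses],
                r_squared=float("nan"),
            )
            raise FitFailureError(f"joint peak refinement failed: {exc}", partial)
        for i in range(0, popt.size, 3):
            centre, height, sigma = popt[i : i + 3]
            # Edge Gaussians (centre within one sigma of the range edge) are
            # unidentifiable; drop them.
            if centre < fmin + sigma or centre > fmax - sigma:
                continue
            peaks.append(SpectralPeak(float(centre), float(height), float(2 * sigma)))
        peaks.sort(key=lambda p: p.centre_freq)

    # (6) refit aperiodic on the peak-removed spectrum.
    peak_model = np.zeros_like(freqs)
    for p in peaks:
        peak_model += p.height * np.exp(-((freqs - p.centre_freq) ** 2) / (2 * p.sigma**2))
    offset, exponent = _robust_aperiodic(log_freqs, log_power - peak_model)

    # (7) goodness of fit on log10 power.
    modelled = (offset - exponent * log_freqs) + peak_model
    if np.allclose(log_power, log_power[0]):
        r_squared = 1.0
    else:
        r_squared = float(np.corrcoef(log_power, modelled)[0, 1] ** 2)

    fit = SpectralFit(
        offset=offset,
        exponent=exponent,
        peaks=peaks,
        r_squared=r_squared,
        settings={
            "max_peaks": max_peaks,
            "peak_threshold_sd": peak_threshold_sd,
            "min_peak_height": min_peak_height,
            "bw_limits": tuple(bw_limits),
        },
    )
    fit.alpha_peak = select_band_peak(fit, ALPHA_BAND)
    fit.beta_peak = select_band_peak(fit, BETA_BAND)
    return fit


def select_band_peak(
    fit: SpectralFit, band: tuple[float, float]
) -> SpectralPeak | None:
    """Highest fitted peak with centre inside ``band``; None when absent.

    Ties on height break towards the lower centre frequency.  Downstream
    models treat subjects with no peak as missing for that band's features.
    """
    lo, hi = band
    candidates = [p for p in fit.peaks if lo <= p.centre_freq <= hi]
    if not candidates:
        return None
    return min(candidates, key=lambda p: (-p.height, p.centre_freq))


def raw_band_peak(
    psd: PowerSpectrum, band: tuple[float, float]
) -> tuple[float, float]:
    """Maximum uncorrected PSD value in ``band`` and its frequency."""
    mask = psd.band_slice(band)
    if not np.any(mask):
        raise InvalidParameterError(f"band {band} contains no frequency bins")
    idx = int(np.argmax(psd.power[mask]))
    return float(psd.power[mask][idx]), float(psd.freqs[mask][idx])
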