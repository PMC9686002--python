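"""Per-epoch featurization: 46 features in four families.

* 18 time-domain HRV statistics on the raw intervals and their successive
  differences (SDNN, RMSSD, SDSD, NN50/pNN50, NN20/pNN20, HR statistics...).
* 20 frequency-domain HRV quantities from a Welch power spectral density of
  the evenly resampled interval series: peak frequency, absolute, log and
  relative power in the VLF (0-0.04 Hz), LF (0.04-0.15 Hz), HF (0.15-0.4 Hz)
  and VHF (0.4-3 Hz) bands, plus normalized LF/HF power, the LF/HF ratio
  and total power.
* 4 nonlinear (Poincare) descriptors: SD1, SD2, their ratio and the fitted
  ellipse area.
* 4 respiration statistics from an ECG-derived respiration signal obtained
  via respiratory sinus arrhythmia: the interval series is resampled at
  4 Hz, band-passed to 0.2-0.8 Hz, breath peaks detected, and the
  inter-breath intervals converted to breaths/min.

Conventions (documented in :data:`FEATURE_DICTIONARY`): sample (n-1)
standard deviations for SDNN/SDSD/HR-SD/respiration-SD; Poincare SD1 is
defined through the uncentred second moment of the successor differences,
which makes the identity ``SD1 = RMSSD / sqrt(2)`` exact; SD2 uses the
centred population variance of the (x+y)/sqrt(2) axis.  Missing values are
carried as NaN sentinels (only respiration features, and log powers of
degenerate constant epochs, can be missing).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError
from .ingest import Epoch

logger = logging.getLogger(__name__)

#: Resampling rate (Hz) for the frequency-domain PSD.  8 Hz, not the 4 Hz
#: used by the respiration stage, because the VHF band extends to 3 Hz and
#: needs Nyquist >= 3 Hz.
PSD_FS = 8.0

#: Resampling rate (Hz) for the ECG-derived respiration stage.
RESP_FS = 4.0

#: Band-pass edges (Hz) isolating respiratory frequencies, i.e. plausible
#: breathing rates of 12-48 breaths/min.
RESP_BAND = (0.2, 0.8)

#: Minimum breath-peak separation (s): the reciprocal of the upper band edge.
MIN_BREATH_SEPARATION_S = 1.25

#: Minimum prominence (ms) for a breath peak in the filtered signal.
#: Genuine RSA leaves tens of ms of in-band modulation, while out-of-band
#: components survive the forward-backward Butterworth only as a few ms of
#: filter edge transient and interpolation harmonics; 5 ms separates the two.
BREATH_PROMINENCE_MS = 5.0

#: Spectral bands (Hz): very-low, low, high and very-high frequency.
BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.0, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.4),
    "vhf": (0.4, 3.0),
}

TIME_DOMAIN_FEATURES = [
    "rri_min", "rri_max", "rri_mean", "rri_count",
    "rridiff_mean", "rridiff_min", "rridiff_max",
    "hr_mean", "hr_min", "hr_max", "hr_sd",
    "sdnn", "rmssd", "sdsd",
    "nn50", "pnn50", "nn20", "pnn20",
]
FREQUENCY_DOMAIN_FEATURES = [
    f"{band}_{kind}"
    for band in BANDS
    for kind in ("peak_freq", "abs_power", "log_power", "rel_power")
] + ["lf_norm", "hf_norm", "lf_hf_ratio", "total_power"]
NONLINEAR_FEATURES = ["sd1", "sd2", "sd_ratio", "ellipse_area"]
RESPIRATION_FEATURES = ["resp_mean", "resp_min", "resp_max", "resp_sd"]

#: Canonical column order of the 46-feature vector.
FEATURE_NAMES = (
    TIME_DOMAIN_FEATURES
    + FREQUENCY_DOMAIN_FEATURES
    + NONLINEAR_FEATURES
    + RESPIRATION_FEATURES
)

#: Feature -> family, for selection and reporting.
FEATURE_FAMILIES = {
    **{f: "time_domain" for f in TIME_DOMAIN_FEATURES},
    **{f: "frequency_domain" for f in FREQUENCY_DOMAIN_FEATURES},
    **{f: "nonlinear" for f in NONLINEAR_FEATURES},
    **{f: "respiration" for f in RESPIRATION_FEATURES},
}

_UNITS = {
    "rri_min": "ms", "rri_max": "ms", "rri_mean": "ms", "rri_count": "count",
    "rridiff_mean": "ms", "rridiff_min": "ms", "rridiff_max": "ms",
    "hr_mean": "bpm", "hr_min": "bpm", "hr_max": "bpm", "hr_sd": "bpm",
    "sdnn": "ms", "rmssd": "ms", "sdsd": "ms",
    "nn50": "count", "pnn50": "%", "nn20": "count", "pnn20": "%",
    "lf_norm": "%", "hf_norm": "%", "lf_hf_ratio": "-", "total_power": "ms^2",
    "sd1": "ms", "sd2": "ms", "sd_ratio": "-", "ellipse_area": "ms^2",
    "resp_mean": "breaths/min", "resp_min": "breaths/min",
    "resp_max": "breaths/min", "resp_sd": "breaths/min",
}
for _b in BANDS:
    _UNITS[f"{_b}_peak_freq"] = "Hz"
    _UNITS[f"{_b}_abs_power"] = "ms^2"
    _UNITS[f"{_b}_log_power"] = "ln(ms^2)"
    _UNITS[f"{_b}_rel_power"] = "%"

#: Machine-readable feature dictionary: name -> (family, units).
FEATURE_DICTIONARY = {
    name: {"family": FEATURE_FAMILIES[name], "units": _UNITS[name]}
    for name in FEATURE_NAMES
}


@dataclass(frozen=True)
class FeatureVector:
    """The 46 named features of one epoch plus its identity."""

    subject_id: str
    condition: str
    epoch_index: int
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"feature vector incomplete: missing {missing}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=float)


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) >= 2 else 0.0


def compute_time_domain(epoch: Epoch) -> dict[str, float]:
    """The 18 time-domain statistics of one epoch.

    Instantaneous HR is 60000/RRI per interval.  RRIdiff statistics are on
    absolute successive differences.  NN50/NN20 count absolute successive
    differences exceeding 50/20 ms; pNN50/pNN20 express them as a
    percentage of the number of successive differences.
    """
    iv = np.asarray(epoch.intervals, dtype=float)
    if len(iv) < 2:
        raise InsufficientDataError("need >= 2 intervals for time-domain HRV")
    diffs = np.diff(iv)
    adiffs = np.abs(diffs)
    hr = 60_000.0 / iv
    nn50 = int(np.count_nonzero(adiffs > 50.0))
    nn20 = int(np.count_nonzero(adiffs > 20.0))
    return {
        "rri_min": float(iv.min()),
        "rri_max": float(iv.max()),
        "rri_mean": float(iv.mean()),
        "rri_count": float(len(iv)),
        "rridiff_mean": float(adiffs.mean()),
        "rridiff_min": float(adiffs.min()),
        "rridiff_max": float(adiffs.max()),
        "hr_mean": float(hr.mean()),
        "hr_min": float(hr.min()),
        "hr_max": float(hr.max()),
        "hr_sd": _sample_sd(hr),
        "sdnn": _sample_sd(iv),
        "rmssd": float(np.sqrt(np.mean(diffs**2))),
        "sdsd": _sample_sd(diffs),
        "nn50": float(nn50),
        "pnn50": 100.0 * nn50 / len(diffs),
        "nn20": float(nn20),
        "pnn20": 100.0 * nn20 / len(diffs),
    }


def _interpolate_uniform(epoch: Epoch, fs: float) -> np.ndarray:
    """Linearly resample the interval series onto a uniform grid spanning
    the epoch window (tachogram interpolation; ends held constant)."""
    n = int(round(epoch.epoch_ms / 1000.0 * fs))
    t = epoch.start_time + np.arange(n) * (1000.0 / fs)
    return np.interp(t, epoch.beat_times, epoch.intervals)


def compute_frequency_domain(epoch: Epoch) -> dict[str, float]:
    """The 20 frequency-domain quantities of one epoch.

    The interval series is resampled at 8 Hz, mean-removed, and a Welch
    PSD is taken over a single epoch-length rectangular segment.  Band
    powers are
    trapezoidal integrals of the PSD over each band; relative powers are
    percentages of the four-band total, so they sum to 100 by construction.
    A constant (zero-variance) series yields zero powers with NaN log
    powers and peak frequencies, reported with a warning.
    """
    iv = np.asarray(epoch.intervals, dtype=float)
    if len(iv) < 2:
        raise InsufficientDataError("need >= 2 intervals for spectral HRV")
    x = _interpolate_uniform(epoch, PSD_FS)
    x = x - x.mean()
    out: dict[str, float] = {}
    if np.ptp(x) == 0:
        logger.warning(
            "%s/%s epoch %d: constant series, spectral powers degenerate",
            epoch.subject_id, epoch.condition, epoch.epoch_index,
        )
        for band in BANDS:
            out[f"{band}_peak_freq"] = math.nan
            out[f"{band}_abs_power"] = 0.0
            out[f"{band}_log_power"] = math.nan
            out[f"{band}_rel_power"] = math.nan
        out.update(
            lf_norm=math.nan, hf_norm=math.nan,
            lf_hf_ratio=math.nan, total_power=0.0,
        )
        return out

    # Single rectangular-window segment: the integrated PSD then preserves
    # the series variance (Parseval), which a tapered single segment of a
    # strongly autocorrelated series does not.
    freqs, psd = sps.welch(
        x, fs=PSD_FS, nperseg=len(x), detrend=False, window="boxcar"
    )
    abs_powers: dict[str, float] = {}
    for band, (lo, hi) in BANDS.items():
        mask = (freqs >= lo) & (freqs <= hi)
        power = float(np.trapezoid(psd[mask], freqs[mask]))
        abs_powers[band] = power
        band_freqs, band_psd = freqs[mask], psd[mask]
        out[f"{band}_peak_freq"] = float(band_freqs[int(np.argmax(band_psd))])
        out[f"{band}_abs_power"] = power
        out[f"{band}_log_power"] = math.log(power) if power > 0 else math.nan

    total = sum(abs_powers.values())
    for band in BANDS:
        out[f"{band}_rel_power"] = 100.0 * abs_powers[band] / total
    lf, hf = abs_powers["lf"], abs_powers["hf"]
    out["lf_norm"] = 100.0 * lf / (lf + hf) if lf + hf > 0 else math.nan
    out["hf_norm"] = 100.0 * hf / (lf + hf) if lf + hf > 0 else math.nan
    out["lf_hf_ratio"] = lf / hf if hf > 0 else math.nan
    out["total_power"] = total
    return out


def compute_nonlinear(epoch: Epoch) -> dict[str, float]:
    """Poincare descriptors SD1, SD2, their ratio and the ellipse area.

    With x the intervals and y their successors: SD1 is the root mean
    square of (y - x)/sqrt(2) (uncentred, so SD1 == RMSSD/sqrt(2) exactly);
    SD2 is the population SD of (y + x)/sqrt(2).  The ellipse area is
    pi * SD1 * SD2.  SD2 == 0 makes the ratio a NaN sentinel.
    """
    iv = np.asarray(epoch.intervals, dtype=float)
    if len(iv) < 3:
        raise InsufficientDataError("need >= 3 intervals for Poincare HRV")
    x, y = iv[:-1], iv[1:]
    sd1 = float(np.sqrt(np.mean(((y - x) / np.sqrt(2.0)) ** 2)))
    sd2 = float(np.std((y + x) / np.sqrt(2.0)))  # population (ddof=0)
    return {
        "sd1": sd1,
        "sd2": sd2,
        "sd_ratio": sd1 / sd2 if sd2 > 0 else math.nan,
        "ellipse_area": math.pi * sd1 * sd2,
    }


def derive_respiration(epoch: Epoch) -> tuple[np.ndarray, dict[str, float]]:
    """ECG-derived respiration from respiratory sinus arrhythmia.

    Pipeline: resample intervals at 4 Hz -> 4th-order Butterworth band-pass
    0.2-0.8 Hz, applied forward-backward (zero phase) -> breath peaks with
    minimum separation 1.25 s and 1 ms prominence -> inter-breath intervals
    -> instantaneous rate 60000/IBI breaths/min.  Fewer than three breaths
    in the epoch yields NaN sentinels with a warning.

    Returns the instantaneous rate series and the four summary features.
    """
    iv = np.asarray(epoch.intervals, dtype=float)
    if len(iv) < 2:
        raise InsufficientDataError("need >= 2 intervals to derive respiration")
    x = _interpolate_uniform(epoch, RESP_FS)
    sos = sps.butter(4, RESP_BAND, btype="bandpass", fs=RESP_FS, output="sos")
    filtered = sps.sosfiltfilt(sos, x - x.mean())
    peaks, _ = sps.find_peaks(
        filtered,
        distance=max(1, int(round(MIN_BREATH_SEPARATION_S * RESP_FS))),
        prominence=BREATH_PROMINENCE_MS,
    )
    if len(peaks) < 3:
        logger.warning(
            "%s/%s epoch %d: %d breath(s) detected, respiration missing",
            epoch.subject_id, epoch.condition, epoch.epoch_index, len(peaks),
        )
        nanfeat = {name: math.nan for name in RESPIRATION_FEATURES}
        return np.array([]), nanfeat
    ibi_ms = np.diff(peaks) / RESP_FS * 1000.0
    rates = 60_000.0 / ibi_ms
    features = {
        "resp_mean": float(rates.mean()),
        "resp_min": float(rates.min()),
        "resp_max": float(rates.max()),
        "resp_sd": _sample_sd(rates),
    }
    return rates, features


def assemble_feature_vector(epoch: Epoch) -> FeatureVector:
    """Compute all four families and assemble the canonical 46-feature
    vector (18 time-domain + 20 frequency-domain + 4 nonlinear +
    4 respiration) for one epoch."""
    values: dict[str, float] = {}
    values.update(compute_time_domain(epoch))
    values.update(compute_frequency_domain(epoch))
    values.update(compute_nonlinear(epoch))
    _, resp = derive_respiration(epoch)
    values.update(resp)
    values = {name: values[name] for name in FEATURE_NAMES}
    return FeatureVector(
        subject_id=epoch.subject_id,
        condition=epoch.condition,
        epoch_index=epoch.epoch_index,
        values=values,
    )
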