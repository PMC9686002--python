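"""Synthetic cohort generator for baseline vs. cold-pressor beat-interval data.

The generative model is deliberately transparent: each beat interval is a
subject-level base (60000/HR ms) plus additive sinusoidal modulation at the
respiratory frequency (respiratory sinus arrhythmia, RSA) and at a low
Mayer-wave-like frequency, plus white jitter:

    I_n = base + A_rsa * sin(2*pi*f_resp*t_n)
               + A_lf  * sin(2*pi*f_lf*t_n + phi) + eps_n

with ``t_n`` the cumulative beat time.  Pain (the cold-pressor segment)
raises the subject's heart rate by a subject-specific delta and shrinks the
RSA amplitude by a multiplicative factor — the two premises (sympathetic
activation, vagal withdrawal) the downstream classifier is built on.
Additive sinusoids keep every feature target analytically checkable, which
an integral-pulse-frequency-modulation model would not.

A simulated cohort mirrors the study design being emulated: each subject
contributes a 5-min seated baseline and an up-to-3-min cold-pressor
segment, with a configurable fraction of subjects stopping the immersion
early (early durations drawn from a truncated normal, mean 1.34 min,
SD 0.44 min, bounded to [1, 3] min).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import InvalidParameterError, SimulationError
from .ingest import ECGTrace, RRISeries

logger = logging.getLogger(__name__)

#: Hard floor for a simulated beat interval (ms).  Hitting it is a modelling
#: error (parameters produced an impossible heart beat), so it raises rather
#: than silently truncating.
MIN_INTERVAL_MS = 300.0


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Durations are minutes; heart rates bpm; modulation amplitudes ms.
    ``dropout_fraction`` is the probability that a subject ends the
    cold-pressor segment early; early durations come from a truncated
    normal with ``dropout_minutes_mean``/``dropout_minutes_sd`` bounded to
    [1, ``cpt_max_minutes``] minutes.
    """

    n_subjects: int = 41
    baseline_minutes: float = 5.0
    cpt_max_minutes: float = 3.0
    dropout_fraction: float = 12.0 / 41.0
    dropout_minutes_mean: float = 1.34
    dropout_minutes_sd: float = 0.44
    hr_baseline_mean: float = 70.0
    hr_baseline_sd: float = 8.0
    pain_hr_delta_mean: float = 15.0
    pain_hr_delta_sd: float = 4.0
    pain_rsa_scale: float = 0.5
    resp_freq: float = 0.25
    rsa_amplitude_ms: float = 40.0
    lf_freq: float = 0.1
    lf_amplitude_ms: float = 25.0
    noise_sd_ms: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        for name in ("baseline_minutes", "cpt_max_minutes", "hr_baseline_mean"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise InvalidParameterError("dropout_fraction must be in [0, 1]")
        if not 0.2 <= self.resp_freq <= 0.8:
            raise InvalidParameterError(
                "resp_freq must lie in [0.2, 0.8] Hz so the simulated "
                "respiration is recoverable by the EDR band-pass"
            )
        if not 0.0 < self.pain_rsa_scale <= 1.0:
            raise InvalidParameterError("pain_rsa_scale must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's segments: exactly one BL, at most one CPT."""

    subject_id: str
    segments: list[tuple[str, RRISeries]]

    def __post_init__(self) -> None:
        conditions = [c for c, _ in self.segments]
        if conditions.count("BL") != 1 or conditions.count("CPT") > 1:
            raise InvalidParameterError(
                "a subject carries exactly one BL and at most one CPT segment"
            )

    def segment(self, condition: str) -> RRISeries | None:
        for c, s in self.segments:
            if c == condition:
                return s
        return None


@dataclass(frozen=True)
class CohortDataset:
    subjects: list[SubjectRecord]
    config: SimulationConfig

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError("subject_ids must be unique")
        if len(ids) != self.config.n_subjects:
            raise InvalidParameterError("cohort length must equal n_subjects")

    def __len__(self) -> int:
        return len(self.subjects)


def simulate_rri_series(
    duration_s: float,
    hr_mean: float,
    rsa_amplitude_ms: float = 40.0,
    resp_freq: float = 0.25,
    lf_amplitude_ms: float = 25.0,
    lf_freq: float = 0.1,
    noise_sd_ms: float = 0.0,
    seed: int = 0,
    subject_id: str = "",
    condition: str = "BL",
) -> RRISeries:
    """Generate one beat-interval series under the additive model.

    The low-frequency component gets a random phase (seeded) so subjects do
    not share Mayer-wave alignment; the RSA component is phase-locked to
    time zero so respiration timing is deterministic given the seed.

    Raises
    ------
    InvalidParameterError
        For non-positive duration or heart rate.
    SimulationError
        If the parameter combination drives any interval below 300 ms.
    """
    if duration_s <= 0 or hr_mean <= 0:
        raise InvalidParameterError("duration and hr_mean must be positive")
    if duration_s < 60:
        raise InvalidParameterError(
            "duration must be >= 60 s for downstream epoching"
        )
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    base = 60_000.0 / hr_mean
    duration_ms = duration_s * 1000.0

    # Beats are laid down until the nominal duration is covered: the final
    # beat is the first to land on or past duration_ms, so a 300-s record
    # really spans five full 60-s epoch windows.
    times = [0.0]
    intervals = []
    t = 0.0
    while t < duration_ms:
        iv = (
            base
            + rsa_amplitude_ms * np.sin(2.0 * np.pi * resp_freq * t / 1000.0)
            + lf_amplitude_ms * np.sin(2.0 * np.pi * lf_freq * t / 1000.0 + phi)
        )
        if noise_sd_ms > 0:
            iv += rng.normal(0.0, noise_sd_ms)
        if iv < MIN_INTERVAL_MS:
            raise SimulationError(
                f"simulated interval {iv:.1f} ms fell below the "
                f"{MIN_INTERVAL_MS:.0f} ms clamp; parameters are implausible"
            )
        t += iv
        times.append(t)
        intervals.append(iv)
    return RRISeries(
        subject_id=subject_id,
        condition=condition,
        beat_times=np.asarray(times),
        intervals=np.asarray(intervals),
    )


def simulate_subject(
    config: SimulationConfig, subject_id: str, seed: int
) -> SubjectRecord:
    """Draw one subject: baseline segment, then a cold-pressor segment with
    the subject's pain response (HR delta added, RSA amplitude scaled)."""
    rng = np.random.default_rng(seed)
    hr_bl = rng.normal(config.hr_baseline_mean, config.hr_baseline_sd)
    hr_bl = max(hr_bl, 40.0)
    pain_delta = rng.normal(config.pain_hr_delta_mean, config.pain_hr_delta_sd)

    drops_out = rng.random() < config.dropout_fraction
    if drops_out:
        a = (1.0 - config.dropout_minutes_mean) / config.dropout_minutes_sd
        b = (config.cpt_max_minutes - config.dropout_minutes_mean) / config.dropout_minutes_sd
        cpt_minutes = float(
            stats.truncnorm.rvs(
                a, b,
                loc=config.dropout_minutes_mean,
                scale=config.dropout_minutes_sd,
                random_state=rng,
            )
        )
    else:
        cpt_minutes = config.cpt_max_minutes

    bl = simulate_rri_series(
        duration_s=config.baseline_minutes * 60.0,
        hr_mean=hr_bl,
        rsa_amplitude_ms=config.rsa_amplitude_ms,
        resp_freq=config.resp_freq,
        lf_amplitude_ms=config.lf_amplitude_ms,
        lf_freq=config.lf_freq,
        noise_sd_ms=config.noise_sd_ms,
        seed=int(rng.integers(2**31)),
        subject_id=subject_id,
        condition="BL",
    )
    cpt = simulate_rri_series(
        duration_s=cpt_minutes * 60.0,
        hr_mean=hr_bl + pain_delta,
        rsa_amplitude_ms=config.rsa_amplitude_ms * config.pain_rsa_scale,
        resp_freq=config.resp_freq,
        lf_amplitude_ms=config.lf_amplitude_ms,
        lf_freq=config.lf_freq,
        noise_sd_ms=config.noise_sd_ms,
        seed=int(rng.integers(2**31)),
        subject_id=subject_id,
        condition="CPT",
    )
    return SubjectRecord(subject_id=subject_id, segments=[("BL", bl), ("CPT", cpt)])


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Simulate the full cohort; per-subject seeds are ``seed + index`` so
    subjects are independent yet individually reproducible."""
    subjects = [
        simulate_subject(config, f"S{idx:03d}", seed=config.seed + idx)
        for idx in range(config.n_subjects)
    ]
    return CohortDataset(subjects=subjects, config=config)


def synthesize_ecg(
    rri: RRISeries, fs: float = 500.0, noise_sd_mv: float = 0.02, seed: int = 0
) -> ECGTrace:
    """Render an RRI series as a synthetic ECG-like trace.

    One stereotyped Gaussian QRS deflection (1 mV, sigma 8 ms) is centred
    at each beat time (shifted by a 1-s lead-in margin) over low-amplitude
    background noise.  The true in-trace beat times are retained so R-peak
    detection can be validated against known truth.  This is a detector test harness, not a
    morphologically realistic PQRST synthesizer.
    """
    if fs < 100:
        raise InvalidParameterError("fs must be >= 100 Hz")
    if len(rri.beat_times) == 0:
        raise InvalidParameterError("empty RRI series")
    rng = np.random.default_rng(seed)
    # 1-s margins so no QRS template is truncated at a trace edge
    offset_ms = 1000.0
    beat_positions = rri.beat_times + offset_ms
    duration_ms = beat_positions[-1] + 1000.0
    n = int(np.ceil(duration_ms / 1000.0 * fs))
    t_ms = np.arange(n) / fs * 1000.0
    x = rng.normal(0.0, noise_sd_mv, size=n) if noise_sd_mv > 0 else np.zeros(n)
    sigma = 8.0  # ms
    for bt in beat_positions:
        lo = np.searchsorted(t_ms, bt - 5 * sigma)
        hi = np.searchsorted(t_ms, bt + 5 * sigma)
        x[lo:hi] += np.exp(-0.5 * ((t_ms[lo:hi] - bt) / sigma) ** 2)
    return ECGTrace(
        fs=fs,
        samples=x,
        subject_id=rri.subject_id,
        condition=rri.condition,
        true_beat_times=beat_positions,
    )
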