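"""Synthetic motor-imagery EEG sessions and pain diaries with known ground truth.

The EEG generator emulates the phenomenology that sensorimotor BCIs decode:
1/f (pink) background noise per channel plus mu (10 Hz) and beta (20 Hz)
rhythm sources at C3 and C4, mixed to neighboring electrodes with a smooth
Gaussian kernel over great-circle scalp distance.  Motor imagery of one hand
attenuates the *contralateral* source (event-related desynchronization): the
rhythm's band power is scaled by ``1 - erd_depth`` for the duration of the
trial.  Every downstream stage — filtering, CSP-LDA calibration, streaming
decoding, ERD/ERS mapping — is testable against this known ground truth.

The pain-diary generator produces per-subject daily records with a
log-normal random subject intercept and per-period multiplicative effects on
paroxysmal pain volume, the structure the longitudinal mixed models assume.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np

from .montage import Montage, standard_montage
from .pain import DayRecord, Episode, PainDiary
from .recording import TASKS, Annotation, EegRecording

#: Which rhythm source is attenuated by each imagery task (contralateral).
ERD_TARGET = {"left_hand": "C4", "right_hand": "C3"}

#: Spatial mixing kernel width (radians of great-circle distance).
MIXING_WIDTH = 0.35


@dataclass(frozen=True)
class SynthEegConfig:
    """Conditions for a synthetic motor-imagery session.

    ``erd_depth`` is the fractional *band-power* attenuation of the targeted
    rhythm source during imagery (0 = no effect); ``snr`` is the ratio of
    total rhythm power (mu + beta) to broadband noise power at the source
    electrode.  ``trial_duration`` must fit the 1-6 s calibration epoch.
    The amplifier rate is not dictated by the protocol; 256 Hz is the
    configurable default.
    """

    sampling_rate: float = 256.0
    n_series: int = 9
    trials_per_task: int = 6
    task_set: tuple = TASKS
    trial_duration: float = 7.0
    inter_trial: float = 2.5
    erd_depth: float = 0.5
    erd_band: tuple = (8.0, 12.0)
    snr: float = 4.0
    noise_rms: float = 10.0   # microvolts
    trial_power_sd: float = 0.05  # trial-to-trial rhythm power variability
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.sampling_rate < 2 * self.erd_band[1]:
            raise ValueError("sampling_rate must be at least twice the upper "
                             "erd_band edge")
        if self.trial_duration < 6.0:
            raise ValueError("trial_duration must be >= 6 s so the 1-6 s "
                             "calibration epoch fits")
        if self.inter_trial < 1.0:
            raise ValueError("inter_trial must be >= 1 s (pre-cue baseline)")
        unknown = set(self.task_set) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown task label(s): {sorted(unknown)}")


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sfreq: float, rms: float) -> np.ndarray:
    """Per-channel 1/f-power noise, flat below 1 Hz, calibrated to ``rms``."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shaping[0] = 0.0
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1) * shaping
    out = np.fft.irfft(spec, n=n_samples, axis=-1)
    out *= rms / np.sqrt(np.mean(out ** 2, axis=-1, keepdims=True))
    return out


def _trial_layout(cfg: SynthEegConfig, rng: np.random.Generator):
    """Seeded-random balanced cue order: each series holds exactly
    ``trials_per_task`` cues of every task."""
    events = []
    t = cfg.inter_trial
    for series in range(cfg.n_series):
        cues = [task for task in cfg.task_set for _ in range(cfg.trials_per_task)]
        rng.shuffle(cues)
        for task in cues:
            events.append(Annotation(onset=t, duration=cfg.trial_duration,
                                     label=task, run=series))
            t += cfg.trial_duration + cfg.inter_trial
    return events, t  # t = total duration


def _synthesize(cfg: SynthEegConfig, montage: Montage, events,
                total_duration: float, rng: np.random.Generator) -> EegRecording:
    """Render pink noise + amplitude-modulated rhythm sources for a cue list."""
    sfreq = cfg.sampling_rate
    n_samples = int(round(total_duration * sfreq))
    n_ch = len(montage)
    data = _pink_noise(rng, n_ch, n_samples, sfreq, cfg.noise_rms)

    # Total rhythm power = snr * noise power, split equally over mu and beta.
    amp = cfg.noise_rms * math.sqrt(cfg.snr)  # per band: amp^2/2 = snr/2 * rms^2
    tt = np.arange(n_samples) / sfreq

    # Per-trial power jitter (gamma, mean 1) shared by both bands of a source.
    shape = 1.0 / max(cfg.trial_power_sd, 1e-12) ** 2
    gains = {ev: rng.gamma(shape, 1.0 / shape, size=2) for ev in events}

    # Burst boundaries: inter-trial gaps and trials are separate segments, and
    # every segment gets a fresh random phase per source and band.  Identical
    # frequencies with a single phase would make the two sources mutually
    # coherent, so mixed mid-channel variance would hinge on one phase
    # realization; per-burst phases emulate the incoherence of real
    # hemispheric rhythms.
    bounds = sorted({0, n_samples}
                    | {int(round(ev.onset * sfreq)) for ev in events}
                    | {int(round((ev.onset + ev.duration) * sfreq))
                       for ev in events})
    segments = list(zip(bounds[:-1], bounds[1:]))

    for src in ("C3", "C4"):
        envelope = np.ones(n_samples)
        for ev in events:
            i0 = int(round(ev.onset * sfreq))
            i1 = int(round((ev.onset + ev.duration) * sfreq))
            g = gains[ev][0 if src == "C3" else 1]
            scale = g
            if ERD_TARGET.get(ev.label) == src:
                scale *= 1.0 - cfg.erd_depth
            envelope[i0:i1] = np.sqrt(scale)
        source = np.zeros(n_samples)
        for f0 in (10.0, 20.0):
            for i0, i1 in segments:
                phase = rng.uniform(0, 2 * np.pi)
                source[i0:i1] += amp * np.sin(
                    2 * np.pi * f0 * tt[i0:i1] + phase)
        source *= envelope
        weights = np.exp(-montage.distances_from(src) ** 2
                         / (2 * MIXING_WIDTH ** 2))
        data += weights[:, None] * source[None, :]

    return EegRecording(data=data, sfreq=sfreq,
                        channel_names=list(montage.channel_names),
                        annotations=list(events))


def generate_mi_session(config: SynthEegConfig | None = None,
                        montage: Montage | None = None) -> EegRecording:
    """Generate one annotated motor-imagery session.

    Returns a recording of ``n_series * trials_per_task * len(task_set)``
    cued trials (162 at protocol defaults: 9 series of 6 trials per task,
    3 tasks).  During ``left_hand`` trials the mu/beta source at C4 is
    attenuated in band power by ``1 - erd_depth`` (C3 for ``right_hand``;
    ``relax`` attenuates nothing).  Bit-identical output for equal seeds.
    """
    cfg = config or SynthEegConfig()
    montage = montage or standard_montage(19)
    rng = np.random.default_rng(cfg.seed)
    events, total = _trial_layout(cfg, rng)
    return _synthesize(cfg, montage, events, total, rng)


def generate_scripted_recording(script, config: SynthEegConfig | None = None,
                                montage: Montage | None = None,
                                lead_in: float = 2.0,
                                seed: int | None = None) -> EegRecording:
    """Render a recording in which the subject holds a scripted sequence of
    mental states.

    ``script`` is a list of ``(label, duration_s)`` pairs; each segment is
    annotated and drives the same ERD machinery as cued trials (without the
    6-s minimum, since no calibration epoching is implied).  Used to
    re-simulate closed-loop exercises offline.
    """
    cfg = config or SynthEegConfig()
    montage = montage or standard_montage(19)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    events, t = [], lead_in
    for label, dur in script:
        if label not in TASKS:
            raise ValueError(f"unknown task label: {label!r}")
        events.append(Annotation(onset=t, duration=float(dur), label=label))
        t += float(dur)
    return _synthesize(cfg, montage, events, t + 0.5, rng)


def inject_artifact(rec: EegRecording, onset: float, duration: float,
                    gain: float = 100.0, seed: int = 0) -> EegRecording:
    """Add a high-variance broadband contaminant (all channels) to a copy of
    the recording; used to exercise outlier-window rejection."""
    out = rec.copy()
    rng = np.random.default_rng(seed)
    i0 = int(round(onset * rec.sfreq))
    i1 = min(int(round((onset + duration) * rec.sfreq)), rec.n_samples)
    scale = gain * np.sqrt(np.mean(rec.data ** 2))
    out.data[:, i0:i1] += rng.standard_normal((rec.n_channels, i1 - i0)) * scale
    return out


# ---------------------------------------------------------------------------
# Pain diaries
# ---------------------------------------------------------------------------

#: Default per-period daily paroxysmal-volume multipliers, chosen to mirror
#: the magnitude of group-level median reductions reported for the study
#: weeks (~ -35/-55/-64/-86 % at w1..w4).
DEFAULT_MULTIPLIERS = {"m-1": 1.0, "w1": 0.65, "w2": 0.45, "w3": 0.36, "w4": 0.14}

DEFAULT_DAYS = {"m-1": 30, "w1": 7, "w2": 7, "w3": 7, "w4": 7}


@dataclass(frozen=True)
class PainSimConfig:
    """Conditions for synthetic pain diaries.

    Per subject ``i`` and period ``p``, daily paroxysmal pain volume is
    ``baseline_volume_median * period_multipliers[p] * exp(b_i) * exp(eps)``
    with ``b_i ~ N(0, subject_sd^2)`` a log-scale random intercept and
    ``eps`` day-to-day log-normal dispersion (``noise_model=("lognormal",
    sigma)``; sigma 0 = dispersion-free).  The period *median* volume is then
    exactly ``baseline_volume_median * multiplier * exp(b_i)``.
    """

    n_subjects: int = 6
    days_per_period: dict = field(default_factory=lambda: dict(DEFAULT_DAYS))
    baseline_volume_median: float = 335.0
    baseline_nrs: float = 5.0
    subject_sd: float = 0.3
    period_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS))
    episode_rate: float = 3.0
    noise_model: tuple = ("lognormal", 0.5)
    seed: int = 0

    def __post_init__(self):
        if any(m <= 0 for m in self.period_multipliers.values()):
            raise ValueError("period multipliers must be positive")
        if any(d < 1 for d in self.days_per_period.values()):
            raise ValueError("each period needs at least one day")
        if self.episode_rate < 0:
            raise ValueError("episode_rate must be >= 0")
        kind, _ = self.noise_model
        if kind != "lognormal":
            raise ValueError("only the 'lognormal' dispersion model is defined")

    @property
    def noise_sigma(self) -> float:
        return float(self.noise_model[1])


def expected_phase_contrast(config: PainSimConfig, weeks) -> float:
    """Population contrast (phase mean minus baseline mean) of the daily
    percent-variation response implied by the generator.

    Daily percent variation is ``100 * (v / baseline_median_i - 1)`` with
    ``v = baseline_median_i * mult * exp(eps)``, so its mean over a period is
    ``100 * (mult * E[exp(eps)] - 1)`` with ``E[exp(eps)] = exp(sigma^2/2)``.
    """
    s2 = config.noise_sigma ** 2
    mults = [config.period_multipliers[w] for w in weeks]
    return 100.0 * math.exp(s2 / 2.0) * (float(np.mean(mults)) - 1.0)


def _split_volume(v: float, rng: np.random.Generator, rate: float):
    """Partition a daily volume into >= 1 episodes (count 1 + Poisson)."""
    if v <= 0:
        return []
    n = 1 + int(rng.poisson(max(rate - 1.0, 0.0)))
    shares = rng.dirichlet(np.ones(n)) if n > 1 else np.array([1.0])
    episodes = []
    for s in shares:
        intensity = float(np.round(rng.uniform(2.0, 9.0) * 2) / 2)
        episodes.append(Episode(intensity=intensity,
                                duration_h=s * v / intensity))
    return episodes


def generate_pain_diaries(config: PainSimConfig | None = None) -> list[PainDiary]:
    """Generate per-subject daily diaries for every configured period.

    NRS triplets always satisfy ``min <= avg <= max``; daily volumes are the
    exact sum of episode intensity x duration.  Reproducible from the seed.
    """
    cfg = config or PainSimConfig()
    rng = np.random.default_rng(cfg.seed)
    sigma = cfg.noise_sigma
    period_order = list(cfg.days_per_period)
    start = _dt.date(2020, 1, 1)
    diaries = []
    for i in range(cfg.n_subjects):
        b_i = rng.normal(0.0, cfg.subject_sd) if cfg.subject_sd > 0 else 0.0
        nrs_off = rng.normal(0.0, 1.0) if sigma > 0 else 0.0
        days, date = [], start
        for period in period_order:
            mult = cfg.period_multipliers.get(period, 1.0)
            target = cfg.baseline_volume_median * mult * math.exp(b_i)
            for _ in range(cfg.days_per_period[period]):
                eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                volume = target * math.exp(eps)
                episodes = _split_volume(volume, rng, cfg.episode_rate)
                avg = cfg.baseline_nrs + nrs_off + 2.0 * (mult - 1.0)
                if sigma > 0:
                    avg += rng.normal(0.0, 0.5)
                avg = float(np.clip(avg, 0.0, 10.0))
                lo = float(np.clip(avg - abs(rng.normal(1.5, 0.5)), 0.0, avg))
                hi = float(np.clip(avg + abs(rng.normal(1.5, 0.5)), avg, 10.0))
                days.append(DayRecord(date=date, period=period, nrs_min=lo,
                                      nrs_avg=avg, nrs_max=hi,
                                      episodes=episodes))
                date += _dt.timedelta(days=1)
        diaries.append(PainDiary(subject_id=f"{i + 1:02d}", days=days))
    return diaries
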