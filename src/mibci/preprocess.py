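"""Deterministic conditioning of raw EEG into labeled windows.

The calibration front end: an 8-30 Hz linear-phase FIR band-pass (the mu
and beta rhythms that modulate during motor imagery), extraction of the
1-6 s post-cue epoch of every trial, segmentation into 2-s windows with 50%
overlap, and robust rejection of outlier windows.

The outlier rule is a documented stand-in (the deployed system's exact
statistic is unpublished): per class and channel the log-variance of each
window is scored with a median/MAD robust z; a window whose maximum score
across channels exceeds ``z_max`` is excluded.  It is applied at
calibration time only, never in the closed loop.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import signal

from .recording import Annotation, EegRecording, LabeledWindowSet

#: Transition width of the windowed-sinc design, Hz.
TRANSITION_HZ = 2.0


def design_bandpass(sfreq: float, low: float = 8.0, high: float = 30.0,
                    transition: float = TRANSITION_HZ) -> np.ndarray:
    """Hamming windowed-sinc band-pass taps.

    Cutoffs sit half a transition width outside the pass band, so the
    response is flat (ripple << 1 dB) on [low, high] and > 40 dB down by
    ``low - transition`` / ``high + transition``.  Order follows the Harris
    approximation for a Hamming window (~53 dB stop band).
    """
    nyq = sfreq / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz must lie inside "
                         f"(0, {nyq}) Hz")
    if low - transition <= 0:
        raise ValueError("transition band extends below 0 Hz")
    numtaps = int(math.ceil(3.3 * sfreq / transition))
    numtaps += 1 - numtaps % 2  # odd -> type-I linear phase
    return signal.firwin(numtaps, [low - transition / 2, high + transition / 2],
                         pass_zero=False, window="hamming", fs=sfreq)


def bandpass_fir(rec: EegRecording, low: float = 8.0,
                 high: float = 30.0) -> EegRecording:
    """Zero-lag FIR band-pass of a recording.

    Single forward pass with group-delay compensation (the taps are
    linear-phase); edges are reflection-padded.  Annotations are untouched.
    """
    taps = design_bandpass(rec.sfreq, low, high)
    pad = len(taps)  # >= group delay
    x = np.pad(rec.data, ((0, 0), (pad, pad)), mode="reflect")
    y = signal.fftconvolve(x, taps[None, :], mode="same", axes=-1)
    out = rec.copy()
    out.data = y[:, pad:-pad]
    return out


def epoch_and_window(rec: EegRecording, annotations=None,
                     epoch_span: tuple = (1.0, 6.0), window: float = 2.0,
                     overlap: float = 0.5) -> LabeledWindowSet:
    """Cut each cued trial into overlapping fixed-length windows.

    The epoch is the half-open span ``[cue + epoch_span[0],
    cue + epoch_span[1])``; windows of ``window`` s advance by
    ``window * (1 - overlap)`` s (defaults: starts at cue+1, +2, +3, +4 s).
    Labels and run ids are inherited from the cue annotation.  Trials that
    do not fully contain the span are skipped with a warning.
    """
    anns = list(rec.annotations if annotations is None else annotations)
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    step = window * (1.0 - overlap)
    span0, span1 = epoch_span
    if span1 - span0 < window:
        raise ValueError("epoch span shorter than one window")
    nwin = int(round(window * rec.sfreq))
    nstep = int(round(step * rec.sfreq))
    wins, labels, trial_id, run_id = [], [], [], []
    for t, ann in enumerate(anns):
        start = ann.onset + span0
        offsets = []
        s = start
        while s + window <= ann.onset + span1 + 1e-9:
            offsets.append(s)
            s += step
        i_last = int(round(offsets[-1] * rec.sfreq)) + nwin
        if i_last > rec.n_samples or ann.onset + span1 > ann.onset + ann.duration + 1e-9:
            warnings.warn(f"trial {t} ({ann.label!r} at {ann.onset:.1f}s) is "
                          "too short for the epoch span; skipped")
            continue
        i0 = int(round(start * rec.sfreq))
        for j in range(len(offsets)):
            a = i0 + j * nstep
            wins.append(rec.data[:, a:a + nwin])
            labels.append(ann.label)
            trial_id.append(t)
            run_id.append(ann.run)
    wins = (np.stack(wins) if wins
            else np.empty((0, rec.n_channels, nwin)))
    return LabeledWindowSet(windows=wins, labels=np.array(labels, dtype=object),
                            trial_id=np.array(trial_id, dtype=int),
                            run_id=np.array(run_id, dtype=int),
                            window_length=window, step=step, sfreq=rec.sfreq,
                            channel_names=list(rec.channel_names))


def _robust_z(x: np.ndarray) -> np.ndarray:
    """Median/MAD z-scores per column; MAD=0 falls back to the standard
    deviation, and a zero spread scores everything 0 (identical data can
    never be outlying)."""
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    sd = np.std(x, axis=0)
    z = np.zeros_like(x)
    use_mad = mad > 0
    z[:, use_mad] = 0.6744897501960817 * (x[:, use_mad] - med[use_mad]) / mad[use_mad]
    use_sd = (~use_mad) & (sd > 0)
    z[:, use_sd] = (x[:, use_sd] - med[use_sd]) / sd[use_sd]
    return z


def reject_outlier_windows(ws: LabeledWindowSet, z_max: float = 3.5):
    """Exclude windows whose class-wise log-variance is robustly outlying.

    Returns the retained window set (order preserved) and a report dict with
    the rejected indices and per-window scores.  Raises if any class would
    be reduced below 2 windows (relax ``z_max`` in that case).
    """
    n = len(ws)
    scores = np.zeros(n)
    logvar = np.log(np.maximum(ws.windows.var(axis=-1, ddof=1), 1e-300))
    for cls in ws.classes:
        idx = np.flatnonzero(ws.labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 windows")
        scores[idx] = np.abs(_robust_z(logvar[idx])).max(axis=1)
    keep = scores <= z_max
    for cls in ws.classes:
        if np.count_nonzero(keep & (ws.labels == cls)) < 2:
            raise ValueError(
                f"rejection at z_max={z_max} leaves class {cls!r} with fewer "
                "than 2 windows; relax the threshold")
    report = {"z_max": float(z_max),
              "n_total": int(n),
              "n_rejected": int(n - keep.sum()),
              "rejected_indices": np.flatnonzero(~keep).tolist(),
              "scores": scores.tolist()}
    return ws.subset(keep), report
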