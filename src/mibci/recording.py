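"""Core containers for annotated multichannel EEG and labeled windows.

An :class:`EegRecording` is the raw material of every signal stage: a
channels x samples array in microvolts with cue annotations.  A
:class:`LabeledWindowSet` is the decoder's training currency: fixed-length
windows with class labels and run/trial provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical task order.  All class orderings (posterior columns, tie-breaks)
#: follow this order; unknown labels sort alphabetically after them.
TASKS = ("relax", "left_hand", "right_hand")


def canonical_class_order(labels) -> list[str]:
    """Order class labels: the canonical motor-imagery tasks first, then others."""
    labels = set(labels)
    ordered = [t for t in TASKS if t in labels]
    ordered += sorted(labels - set(TASKS))
    return ordered


@dataclass(frozen=True)
class Annotation:
    """A task cue: onset and duration in seconds from recording start."""

    onset: float
    duration: float
    label: str
    run: int = 0


@dataclass
class EegRecording:
    """Annotated multichannel EEG time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sfreq : float
        Sampling rate in Hz.
    channel_names : list of str
        One label per row of ``data``.
    annotations : list of Annotation
        Task cues, onsets in seconds from the start of the recording.
    """

    data: np.ndarray
    sfreq: float
    channel_names: list[str]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names were given"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.sfreq > 0:
            raise ValueError("sampling rate must be positive")
        for ann in self.annotations:
            if ann.onset < 0 or ann.onset + ann.duration > self.duration + 1e-9:
                raise ValueError(
                    f"annotation {ann.label!r} at {ann.onset:.3f}s "
                    "lies outside the recording"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.sfreq

    def copy(self) -> "EegRecording":
        return replace(self, data=self.data.copy(),
                       channel_names=list(self.channel_names),
                       annotations=list(self.annotations))


@dataclass
class LabeledWindowSet:
    """Fixed-length labeled windows with trial/run provenance.

    ``windows`` is the (n_windows x n_channels x n_samples) stack the
    calibration pipeline produces; ``trial_id``/``run_id`` record which cued
    trial and which series every window came from so that cross-validation
    can fold by run.
    """

    windows: np.ndarray
    labels: np.ndarray
    trial_id: np.ndarray
    run_id: np.ndarray
    window_length: float
    step: float
    sfreq: float
    channel_names: list[str]

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.trial_id = np.asarray(self.trial_id, dtype=int)
        self.run_id = np.asarray(self.run_id, dtype=int)
        if self.windows.ndim != 3:
            raise ValueError("windows must be 3-D (n, channels, samples)")
        n = self.windows.shape[0]
        if not (len(self.labels) == len(self.trial_id) == len(self.run_id) == n):
            raise ValueError("labels/trial_id/run_id must match window count")
        if self.windows.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def classes(self) -> list[str]:
        return canonical_class_order(np.unique(self.labels))

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.run_id)

    def subset(self, index) -> "LabeledWindowSet":
        """Return a window subset (order preserved); never edits windows."""
        return LabeledWindowSet(
            windows=self.windows[index],
            labels=self.labels[index],
            trial_id=self.trial_id[index],
            run_id=self.run_id[index],
            window_length=self.window_length,
            step=self.step,
            sfreq=self.sfreq,
            channel_names=list(self.channel_names),
        )
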