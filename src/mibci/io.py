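"""Formats and run configuration.

EEG interchange: recordings are read from European Data Format (EDF, via
MNE-Python's reader, annotations included) or from the package's native
session container — a raw ``.npy`` array (channels x samples, microvolts)
with a JSON sidecar carrying the rate, channel labels and annotations.  The
container is byte-deterministic, which EDF writing would not be here.

:class:`RunConfig` gathers every numeric protocol constant of the pipeline
(band, windows, epoch span, update step, fold rule, gate threshold) in one
serializable place; its defaults are the deployed protocol's values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .recording import Annotation, EegRecording


@dataclass(frozen=True)
class RunConfig:
    """Protocol constants; defaults are the study's operating point."""

    band: tuple = (8.0, 30.0)          # Hz, FIR band-pass
    window: float = 2.0                # s, analysis window
    calibration_overlap: float = 0.5   # sliding-window overlap, open loop
    stream_step: float = 0.0625        # s, closed-loop update (16/s)
    epoch_span: tuple = (1.0, 6.0)     # s post-cue, calibration epoch
    baseline: tuple = (-1.0, 0.0)      # s, ERD/ERS reference interval
    k: int | str = "auto"              # CV folds; "auto" = number of runs
    gate_threshold: float = 0.70       # competence-gate accuracy
    n_components: int = 6              # CSP filters retained
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        for key in ("band", "epoch_span", "baseline"):
            d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Session container (.npy + .json sidecar)
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_session(rec: EegRecording, path) -> Path:
    """Write a recording as ``path`` (.npy data) + ``.json`` sidecar.

    Deterministic: identical recordings produce byte-identical files.
    """
    path = Path(path).with_suffix(".npy")
    np.save(path, rec.data)
    meta = {"format": "mibci-session-1", "sfreq": rec.sfreq,
            "channel_names": list(rec.channel_names),
            "annotations": [[a.onset, a.duration, a.label, a.run]
                            for a in rec.annotations]}
    _sidecar(path).write_text(json.dumps(meta, indent=0))
    return path


def read_session(path) -> EegRecording:
    path = Path(path).with_suffix(".npy")
    data = np.load(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta.get("format") != "mibci-session-1":
        raise ValueError(f"{_sidecar(path)}: not a session sidecar")
    anns = [Annotation(onset=o, duration=d, label=l, run=int(r))
            for o, d, l, r in meta["annotations"]]
    return EegRecording(data=data, sfreq=float(meta["sfreq"]),
                        channel_names=list(meta["channel_names"]),
                        annotations=anns)


def read_edf(path, runs_of: int | None = None) -> EegRecording:
    """Read an EDF recording (data in microvolts) with its annotations.

    EDF carries no run structure; ``runs_of`` assigns consecutive
    annotations to runs in blocks of that size (e.g. 18 trials per series).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE uses volts
    anns = []
    for i, (onset, dur, desc) in enumerate(zip(
            raw.annotations.onset, raw.annotations.duration,
            raw.annotations.description)):
        run = i // runs_of if runs_of else 0
        anns.append(Annotation(onset=float(onset), duration=float(dur),
                               label=str(desc), run=run))
    return EegRecording(data=data, sfreq=float(raw.info["sfreq"]),
                        channel_names=list(raw.ch_names), annotations=anns)


def read_recording(path, **kwargs) -> EegRecording:
    """Dispatch on extension: ``.edf`` via MNE, else the native container."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path, **kwargs)
    return read_session(path)


def write_tfmap(tfmap, path) -> Path:
    """ERD/ERS map container: ``.npz`` values + JSON axes sidecar."""
    path = Path(path).with_suffix(".npz")
    np.savez(path, values=tfmap.values)
    meta = {"format": "mibci-tfmap-1",
            "freq_axis": tfmap.freq_axis.tolist(),
            "time_axis": tfmap.time_axis.tolist(),
            "channel_names": list(tfmap.channel_names),
            "baseline_interval": list(tfmap.baseline_interval)}
    _sidecar(path).write_text(json.dumps(meta))
    return path
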