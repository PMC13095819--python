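"""Scalp montages: 10-10 electrode labels with unit-sphere positions.

Positions come from the idealized 10-05 layout bundled with MNE-Python and
are projected onto the unit sphere; distances between electrodes are
great-circle (radian) distances on that sphere.  The default desk-scale
montage is the 19-channel 10-20 set; 32- and 64-channel 10-10 supersets are
available, all containing the sensorimotor triplet C3/Cz/C4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

REQUIRED = ("C3", "Cz", "C4")

_NAMES_19 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]

_NAMES_32 = _NAMES_19 + [
    "AF3", "AF4", "FC5", "FC1", "FC2", "FC6", "CP5", "CP1", "CP2",
    "CP6", "PO3", "PO4", "Oz",
]

_NAMES_64 = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "Iz",
    "T9", "T10",
]


@dataclass(frozen=True)
class Montage:
    """Electrode layout: unique 10-10 labels and unit-sphere 3-D positions."""

    channel_names: tuple
    positions: np.ndarray  # (n, 3), unit radius

    def __post_init__(self):
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("montage channel names must be unique")
        missing = [ch for ch in REQUIRED if ch not in self.channel_names]
        if missing:
            raise ValueError(f"montage must contain {REQUIRED}; missing {missing}")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.channel_names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        radii = np.linalg.norm(pos, axis=1)
        if np.any(np.abs(radii - 1.0) > 1e-9):
            raise ValueError("positions must be normalized to unit radius")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    def distances_from(self, name: str) -> np.ndarray:
        """Great-circle distance (rad) of every electrode from ``name``."""
        ref = self.positions[self.index(name)]
        cos = np.clip(self.positions @ ref, -1.0, 1.0)
        return np.arccos(cos)

    def neighbors(self, name: str, k: int) -> list[str]:
        """The ``k`` electrodes nearest to ``name`` (excluding itself)."""
        order = np.argsort(self.distances_from(name))
        return [self.channel_names[i] for i in order[1:k + 1]]


def _mne_positions(names) -> np.ndarray:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    pos = std.get_positions()["ch_pos"]
    out = np.array([pos[n] for n in names], dtype=float)
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def standard_montage(n_channels: int = 19) -> Montage:
    """A standard 10-10 montage with 19, 32 or 64 channels.

    19 is the desk-scale default; 64 mirrors a full clinical cap.
    """
    names = {19: _NAMES_19, 32: _NAMES_32, 64: _NAMES_64}.get(n_channels)
    if names is None:
        raise ValueError("n_channels must be one of 19, 32, 64")
    return Montage(tuple(names), _mne_positions(names))


def montage_from_names(names) -> Montage:
    """Build a montage from arbitrary 10-10 labels (must include C3/Cz/C4)."""
    return Montage(tuple(names), _mne_positions(list(names)))
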