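"""Core containers: recordings, stage annotations and 30 s multichannel frames.

A *frame* is one scoring epoch of polysomnography: a fixed-duration window
(30 s by convention) of all EEG channels, carrying at most one sleep-stage
label.  Sleep stages follow the R&K nomenclature used by the CAP database:
wake (S0), the four NREM stages S1-S4, and REM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognised R&K stage labels (anything else is an unscored/movement epoch).
STAGES = ("S0", "S1", "S2", "S3", "S4", "REM")

#: Aliases seen in CAP annotation exports, mapped onto the canonical labels.
STAGE_ALIASES = {
    "W": "S0",
    "WAKE": "S0",
    "S0": "S0",
    "S1": "S1",
    "S2": "S2",
    "S3": "S3",
    "S4": "S4",
    "R": "REM",
    "REM": "REM",
}


def canonical_stage(label: str) -> str | None:
    """Map a raw annotation label onto one of the six canonical stages.

    Returns None for unscored / movement / unknown labels.
    """
    return STAGE_ALIASES.get(str(label).strip().upper())


@dataclass
class Recording:
    """A gain-normalised multichannel EEG recording.

    Attributes
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Signal in microvolts (raw integers already divided by the gain).
    fs : float
        Sampling rate in Hz, shared by all channels.
    channels : list of str
        Channel labels, in the order of the columns of ``data``.
    gain : float
        The gain the raw amplitudes were divided by (1.0 means untouched).
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    gain: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (samples x channels)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[1]} signal columns but "
                f"{len(self.channels)} channel labels"
            )
        if self.data.shape[1] < 1:
            raise ValueError("recording needs at least one channel")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class StageAnnotation:
    """Stage label for one scoring epoch (0-based epoch index)."""

    epoch: int
    stage: str

    def __post_init__(self) -> None:
        if self.epoch < 0:
            raise ValueError("epoch index must be non-negative")


@dataclass
class MultichannelFrame:
    """One scoring epoch: ``window_s * fs`` samples of every channel.

    ``stage`` is the attached sleep-stage label, or None when unlabelled.
    """

    data: np.ndarray
    fs: float
    channels: list[str] = field(default_factory=list)
    stage: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("frame data must be 2-D (samples x channels)")
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.data.shape[1])]
        if np.isnan(self.data).any():
            raise ValueError("frame contains NaN samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]
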