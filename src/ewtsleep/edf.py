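"""Reading EDF recordings and per-epoch stage annotations; frame segmentation.

Recordings are read with MNE's EDF reader, restricted to a named channel
subset at a single sampling rate, and amplitude-normalized by dividing out
the recording gain (CAP database exports use a fixed gain of 32.76).
Annotations arrive as delimited text with ``epoch,stage`` columns, one row
per 30 s scoring epoch, 0-based; epoch k of the annotation file maps to
frame k of the signal.  Unrecognized labels (movement/unscored epochs) are
dropped with a warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import MultichannelFrame, Recording, StageAnnotation, canonical_stage

logger = logging.getLogger(__name__)

#: Channels common to all 512 Hz CAP recordings, in pipeline order.
DEFAULT_CHANNELS = ("F4-C4", "C4-P4", "P4-O2", "C4-A1")

#: Amplitude gain of the CAP database EDF exports.
DEFAULT_GAIN = 32.76


def load_recording(
    path: str | Path,
    channels=DEFAULT_CHANNELS,
    gain: float = DEFAULT_GAIN,
    expected_fs: float | None = None,
) -> Recording:
    """Read named channels from an EDF file and divide out the gain.

    Parameters
    ----------
    path : path to an EDF file.
    channels : labels to extract, defining the column order of the result.
    gain : every sample is divided by this scalar (1.0 leaves data untouched).
    expected_fs : reject the file if its sampling rate differs (no resampling).

    Raises
    ------
    KeyError if a requested channel is absent;
    ValueError on mixed sampling rates or an unexpected rate.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    missing = [ch for ch in channels if ch not in raw.ch_names]
    if missing:
        raise KeyError(
            f"channel(s) {missing} not found in {path.name}; "
            f"available: {raw.ch_names}"
        )
    # EDF allows per-signal rates; MNE resamples mismatched channels to the
    # max and warns. Guard against that by checking the declared rates.
    orig_rates = raw._raw_extras[0].get("n_samps") if raw._raw_extras else None
    raw = raw.pick(list(channels)).load_data(verbose="error")
    fs = float(raw.info["sfreq"])
    if orig_rates is not None:
        picked = np.asarray(orig_rates, dtype=float)
        if picked.size and len(set(picked[picked > 0])) > 1:
            sel = [raw.ch_names.index(ch) for ch in channels if ch in raw.ch_names]
            if len({picked[i] for i in sel if i < picked.size}) > 1:
                raise ValueError(
                    f"requested channels in {path.name} have mixed sampling rates"
                )
    if expected_fs is not None and abs(fs - expected_fs) > 1e-6:
        raise ValueError(
            f"{path.name} sampled at {fs} Hz, expected {expected_fs} Hz "
            "(resampling is not performed)"
        )
    if gain <= 0:
        raise ValueError("gain must be positive")
    # MNE scales EEG to volts; EDF physical units here are microvolts
    data = raw.get_data(units="uV").T / gain
    return Recording(data=data, fs=fs, channels=list(channels), gain=gain)


def load_annotations(path: str | Path) -> list[StageAnnotation]:
    """Read ``epoch,stage`` delimited text into stage annotations.

    Unrecognized stage labels are kept verbatim here; they are filtered (with
    a warning) during segmentation so the caller can see what was dropped.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    if "epoch" not in cols or "stage" not in cols:
        raise ValueError("annotation file must have 'epoch' and 'stage' columns")
    return [
        StageAnnotation(epoch=int(row[cols["epoch"]]), stage=str(row[cols["stage"]]).strip())
        for _, row in df.iterrows()
    ]


def segment_frames(
    rec: Recording,
    annotations: list[StageAnnotation] | None = None,
    window_s: float = 30.0,
    epoch_offset: int = 0,
) -> list[MultichannelFrame]:
    """Cut a recording into non-overlapping labeled frames.

    Frame k spans samples [k*window_s*fs, (k+1)*window_s*fs); a trailing
    partial window is discarded.  When annotations are given, annotation
    epoch k (plus ``epoch_offset``) labels frame k and frames without a
    recognized stage label are dropped.  Without annotations all frames are
    returned unlabeled.
    """
    n_win = window_s * rec.fs
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError("window_s * fs must be an integer sample count")
    n_win = int(round(n_win))
    n_frames = rec.n_samples // n_win

    stage_by_epoch: dict[int, str] = {}
    if annotations is not None:
        for ann in annotations:
            stage = canonical_stage(ann.stage)
            if stage is None:
                logger.warning(
                    "dropping epoch %d: unrecognized stage label %r",
                    ann.epoch, ann.stage,
                )
                continue
            stage_by_epoch[ann.epoch + epoch_offset] = stage

    frames = []
    for k in range(n_frames):
        if annotations is not None and k not in stage_by_epoch:
            continue
        data = rec.data[k * n_win : (k + 1) * n_win]
        frames.append(
            MultichannelFrame(
                data=data,
                fs=rec.fs,
                channels=list(rec.channels),
                stage=stage_by_epoch.get(k),
            )
        )
    return frames


def save_frames(frames: list[MultichannelFrame], directory: str | Path) -> None:
    """Persist frames as one CSV each plus an index file with stage labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for i, fr in enumerate(frames):
        name = f"frame_{i:05d}.csv"
        pd.DataFrame(fr.data, columns=fr.channels).to_csv(
            directory / name, index=False
        )
        index.append({"file": name, "fs": fr.fs, "stage": fr.stage or ""})
    pd.DataFrame(index).to_csv(directory / "frames_index.csv", index=False)


def load_frames(directory: str | Path) -> list[MultichannelFrame]:
    """Load frames written by :func:`save_frames`."""
    directory = Path(directory)
    index = pd.read_csv(directory / "frames_index.csv", keep_default_na=False)
    frames = []
    for _, row in index.iterrows():
        df = pd.read_csv(directory / row["file"])
        frames.append(
            MultichannelFrame(
                data=df.to_numpy(),
                fs=float(row["fs"]),
                channels=list(df.columns),
                stage=row["stage"] or None,
            )
        )
    return frames
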