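"""Shared fixtures: a minimal EDF writer, small filter banks and frames.

EDF fixtures are synthesized at test time — nothing binary is stored in the
repository.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from ewtsleep import MultichannelFrame, build_filterbank


def write_minimal_edf(
    path: Path,
    signals: np.ndarray,
    fs: float,
    labels: list[str],
    physical_range: tuple[float, float] = (-1000.0, 1000.0),
) -> None:
    """Write a bare-bones EDF file (one data record per second).

    ``signals`` is (n_samples, n_channels) in physical units (microvolts).
    Values are quantized to 16-bit integers over ``physical_range``; choose a
    range comfortably wider than the data to keep quantization error small.
    """
    n_samples, n_ch = signals.shape
    spr = int(fs)  # samples per record at 1 s records
    n_records = n_samples // spr
    assert n_records * spr == n_samples, "signal must be a whole number of seconds"

    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767

    header = b""
    header += b"0".ljust(8)
    header += b"X".ljust(80)  # patient id
    header += b"X".ljust(80)  # recording id
    header += b"01.01.20".ljust(8)
    header += b"00.00.00".ljust(8)
    header += str(256 + n_ch * 256).encode().ljust(8)
    header += b"".ljust(44)
    header += str(n_records).encode().ljust(8)
    header += b"1".ljust(8)  # record duration s
    header += str(n_ch).encode().ljust(4)

    def field(values, width):
        return b"".join(str(v).encode().ljust(width) for v in values)

    header += field(labels, 16)
    header += field(["" for _ in labels], 80)  # transducer
    header += field(["uV" for _ in labels], 8)
    header += field([pmin for _ in labels], 8)
    header += field([pmax for _ in labels], 8)
    header += field([dmin for _ in labels], 8)
    header += field([dmax for _ in labels], 8)
    header += field(["" for _ in labels], 80)  # prefiltering
    header += field([spr for _ in labels], 8)
    header += field(["" for _ in labels], 32)  # reserved

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((signals - pmin) * scale + dmin), dmin, dmax
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[r * spr : (r + 1) * spr]  # (spr, n_ch)
            for ch in range(n_ch):
                fh.write(block[:, ch].tobytes())


@pytest.fixture
def edf_factory(tmp_path):
    """Callable writing a synthetic EDF and returning its path."""

    def make(signals, fs, labels, name="test.edf", physical_range=(-1000.0, 1000.0)):
        path = tmp_path / name
        write_minimal_edf(path, np.asarray(signals, float), fs, labels,
                          physical_range)
        return path

    return make


@pytest.fixture(scope="session")
def small_bank():
    """Rhythm-edge bank on a short 2 s grid at 512 Hz (fast decompositions)."""
    return build_filterbank(n=1024, fs=512.0)


@pytest.fixture(scope="session")
def full_bank():
    """The reference 30 s / 512 Hz bank (15360-point grid)."""
    return build_filterbank(n=15360, fs=512.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_frame(data, fs=512.0, stage=None):
    return MultichannelFrame(np.asarray(data, float), fs=fs, stage=stage)
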