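"""Synthetic multichannel EEG epochs with stage-dependent rhythm content.

Each sleep stage is described by a :class:`StageTemplate`: relative power
weights over the five classical rhythm bands (delta 0-4 Hz, theta 4-8, alpha
8-13, beta 13-30, gamma 30-75), plus a broadband white-noise fraction, an
amplitude scale and an optional spindle-burst component.  An epoch is a sum
of band-limited Gaussian noise components (one per rhythm), white noise, and
bursts, shared across channels through a common latent source mixed with
channel-specific noise at a configurable correlation.

Each rhythm component is *spectrally peaked* — a Gaussian bump at a
stage-specific centre frequency, truncated to its band — rather than flat
across the band.  This matters: the entropy features downstream are invariant
to amplitude, so stages that differed only in band power with identical
in-band spectral shape would be indistinguishable.  Peak position and
bandwidth, together with the flat white-noise floor the weights are mixed
against, give each stage a distinct in-band structure that the dispersion and
bubble entropies can resolve.

What this generator does NOT emulate: K-complex morphology, artifacts,
non-stationarity within an epoch, inter-subject variability, or 1/f
background scaling.  A pipeline that separates these synthetic stages is
demonstrated to propagate band-structure differences end to end; that is a
necessary, not sufficient, condition for performance on clinical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .frames import STAGES, MultichannelFrame

#: (low, high) Hz edges of the five rhythm bands.
RHYTHM_BANDS = ((0.0, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 75.0))


@dataclass(frozen=True)
class StageTemplate:
    """Spectral recipe for one sleep stage.

    ``weights`` are relative powers over (delta, theta, alpha, beta, gamma)
    and must sum to 1.  ``peaks_hz``/``widths_hz`` give the centre and
    standard deviation of the Gaussian spectral bump of each band component.
    ``noise_fraction`` is the share of total power given to broadband white
    noise.  ``spindle_hz``/``spindle_rate`` add sinusoidal bursts (rate =
    expected bursts per epoch); rate 0 disables them.
    """

    stage: str
    weights: tuple[float, float, float, float, float]
    peaks_hz: tuple[float, float, float, float, float] = (1.5, 6.0, 10.0, 20.0, 40.0)
    widths_hz: tuple[float, float, float, float, float] = (1.0, 1.2, 1.5, 5.0, 12.0)
    noise_fraction: float = 0.3
    amplitude_uv: float = 30.0
    spindle_hz: float = 13.5
    spindle_rate: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size != 5 or (w < 0).any():
            raise ValueError("weights must be 5 non-negative numbers")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("band weights must sum to 1")
        if not 0 <= self.noise_fraction <= 1:
            raise ValueError("noise fraction must lie in [0, 1]")


def default_templates() -> dict[str, StageTemplate]:
    """Stage recipes following the classical polysomnographic picture.

    Wake: alpha/beta dominant, irregular (broad bumps).  S1: theta dominant.
    S2: theta plus 12-14 Hz spindle bursts.  S3/S4: delta dominant, S4 more so
    and more rhythmic (narrower delta bump).  REM: mixed theta/beta at low
    amplitude, wake-like but with its own spectral balance.
    """
    return {
        "S0": StageTemplate(
            stage="S0",
            weights=(0.08, 0.12, 0.40, 0.30, 0.10),
            peaks_hz=(1.5, 6.0, 10.0, 20.0, 40.0),
            widths_hz=(1.5, 1.5, 1.0, 6.0, 15.0),
            amplitude_uv=30.0,
        ),
        "S1": StageTemplate(
            stage="S1",
            weights=(0.15, 0.55, 0.15, 0.10, 0.05),
            peaks_hz=(1.5, 5.5, 9.0, 18.0, 38.0),
            widths_hz=(1.2, 1.0, 1.5, 5.0, 12.0),
            amplitude_uv=35.0,
        ),
        "S2": StageTemplate(
            stage="S2",
            weights=(0.22, 0.42, 0.12, 0.19, 0.05),
            peaks_hz=(1.2, 5.0, 9.5, 14.0, 36.0),
            widths_hz=(0.9, 1.3, 1.8, 3.0, 11.0),
            amplitude_uv=45.0,
            spindle_rate=6.0,
        ),
        "S3": StageTemplate(
            stage="S3",
            weights=(0.58, 0.20, 0.10, 0.08, 0.04),
            peaks_hz=(1.2, 5.0, 9.0, 16.0, 35.0),
            widths_hz=(0.8, 1.2, 1.6, 4.5, 11.0),
            amplitude_uv=70.0,
        ),
        "S4": StageTemplate(
            stage="S4",
            weights=(0.78, 0.10, 0.05, 0.04, 0.03),
            peaks_hz=(0.7, 4.8, 8.8, 15.0, 34.0),
            widths_hz=(0.4, 1.0, 1.4, 4.0, 10.0),
            amplitude_uv=90.0,
        ),
        "REM": StageTemplate(
            stage="REM",
            weights=(0.12, 0.33, 0.12, 0.31, 0.12),
            peaks_hz=(2.0, 6.5, 10.5, 24.0, 45.0),
            widths_hz=(1.3, 2.2, 2.5, 8.0, 18.0),
            amplitude_uv=20.0,
        ),
    }


@dataclass
class SynthConfig:
    """Generator settings: stage templates, geometry, correlation and seed."""

    templates: dict[str, StageTemplate] = field(default_factory=default_templates)
    n_channels: int = 4
    fs: float = 512.0
    epoch_s: float = 30.0
    epochs_per_stage: int = 60
    channel_correlation: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.fs * self.epoch_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * epoch_s must be an integer sample count")
        if not 0 <= self.channel_correlation < 1:
            raise ValueError("channel correlation must lie in [0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_s))


def _band_noise(rng: np.ndarray, n: int, fs: float, lo: float, hi: float,
                peak: float, width: float) -> np.ndarray:
    """Unit-power Gaussian noise with a Gaussian spectral bump inside [lo, hi).

    Shaped directly in the frequency domain so the band content aligns
    exactly with the analysis filter edges.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.exp(-0.5 * ((freqs - peak) / width) ** 2)
    shape[(freqs < lo) | (freqs >= hi)] = 0.0
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec * shape, n=n)
    power = (x**2).mean()
    return x / np.sqrt(power) if power > 0 else x


def _spindle_bursts(rng, n: int, fs: float, freq_hz: float, rate: float) -> np.ndarray:
    """Hann-windowed sinusoidal bursts (~1 s) at Poisson-random onsets, unit power."""
    x = np.zeros(n)
    n_bursts = rng.poisson(rate)
    burst_len = int(fs)  # 1 s bursts
    win = np.hanning(burst_len)
    for _ in range(n_bursts):
        start = rng.integers(0, max(1, n - burst_len))
        t = np.arange(burst_len) / fs
        phase = rng.uniform(0, 2 * np.pi)
        x[start : start + burst_len] += win * np.sin(2 * np.pi * freq_hz * t + phase)
    power = (x**2).mean()
    return x / np.sqrt(power) if power > 0 else x


def _one_source(rng, template: StageTemplate, n: int, fs: float) -> np.ndarray:
    """One realization of the template's spectral recipe, unit-power."""
    banded = np.zeros(n)
    for w, (lo, hi), peak, width in zip(
        template.weights, RHYTHM_BANDS, template.peaks_hz, template.widths_hz
    ):
        if w > 0:
            banded += np.sqrt(w) * _band_noise(rng, n, fs, lo, hi, peak, width)
    if template.spindle_rate > 0:
        burst = _spindle_bursts(rng, n, fs, template.spindle_hz, template.spindle_rate)
        banded = np.sqrt(0.85) * banded + np.sqrt(0.15) * burst
    nf = template.noise_fraction
    x = np.sqrt(1 - nf) * banded
    if nf > 0:
        x = x + np.sqrt(nf) * rng.standard_normal(n)
    return x


def generate_frame(rng, template: StageTemplate, n_channels: int = 4,
                   fs: float = 512.0, epoch_s: float = 30.0,
                   correlation: float = 0.7,
                   channels: list[str] | None = None) -> MultichannelFrame:
    """One labeled epoch: common latent source + channel-specific realizations."""
    n = int(round(fs * epoch_s))
    common = _one_source(rng, template, n, fs)
    data = np.empty((n, n_channels))
    c = correlation
    for ch in range(n_channels):
        own = _one_source(rng, template, n, fs)
        data[:, ch] = np.sqrt(c) * common + np.sqrt(1 - c) * own
    data *= template.amplitude_uv
    return MultichannelFrame(data=data, fs=fs, channels=channels or [],
                             stage=template.stage)


def generate(config: SynthConfig) -> list[MultichannelFrame]:
    """Generate ``epochs_per_stage`` labeled frames for every template stage.

    Deterministic given ``config.seed``; stages are generated in canonical
    order (S0, S1, S2, S3, S4, REM) where present.
    """
    rng = np.random.default_rng(config.seed)
    frames: list[MultichannelFrame] = []
    order = [s for s in STAGES if s in config.templates]
    order += [s for s in config.templates if s not in STAGES]
    for stage in order:
        tpl = config.templates[stage]
        for _ in range(config.epochs_per_stage):
            frames.append(
                generate_frame(
                    rng, tpl, config.n_channels, config.fs, config.epoch_s,
                    config.channel_correlation,
                )
            )
    return frames


def identical_templates(reference: str = "S2") -> dict[str, StageTemplate]:
    """Copy one stage's recipe onto every stage (a no-signal control)."""
    base = default_templates()[reference]
    return {s: replace(base, stage=s, spindle_rate=0.0) for s in STAGES}
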