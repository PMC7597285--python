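"""Multivariate fixed-boundary empirical wavelet filter bank.

The empirical wavelet transform (EWT) builds a Meyer-type wavelet filter bank
whose band edges sit at boundary points of the signal spectrum.  Here the
boundaries are *fixed* at the canonical EEG rhythm edges (4, 8, 13, 30, 75 Hz
by default) instead of being detected from the spectrum, so the bank depends
only on the sampling rate and frame length, never on the data.  Each channel
of a multichannel frame is filtered by every band to produce a samples x
channels x modes tensor whose modes are the delta, theta, alpha, beta and
gamma rhythms plus a residual high band.

The multivariate flavour projects all channels onto a single direction before
any (data-adaptive) boundary analysis; with fixed boundaries the projection
does not influence the bank, but it is exposed because it defines the
composite signal the construction is derived from.

The filters form a tight frame: the squared frequency responses sum to one at
every DFT bin, so analysis followed by synthesis reconstructs the input
exactly (up to floating-point error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import MultichannelFrame

#: Rhythm-band edges (Hz) used to pin the filter boundaries.
DEFAULT_FREQS_HZ = (4.0, 8.0, 13.0, 30.0, 75.0)

#: Names of the six sub-bands the default bank produces.
BAND_LABELS = ("delta", "theta", "alpha", "beta", "gamma", "high")


def projection_weights(n_channels: int, mode: str = "literal") -> np.ndarray:
    """Equal projection weights for all channels.

    mode="literal" uses 1/m per channel; mode="unit-norm" uses 1/sqrt(m),
    which places the direction vector on the unit sphere (sum of squares 1).
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    if mode == "literal":
        return np.full(n_channels, 1.0 / n_channels)
    if mode == "unit-norm":
        return np.full(n_channels, 1.0 / np.sqrt(n_channels))
    raise ValueError(f"unknown projection mode {mode!r}")


def project(frame: MultichannelFrame, weights: np.ndarray) -> np.ndarray:
    """Project a multichannel frame onto a direction vector.

    Returns the weighted sum of channels, Pr(n) = sum_i w_i * x_i(n).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (frame.n_channels,):
        raise ValueError(
            f"{weights.size} weights for {frame.n_channels} channels"
        )
    return frame.data @ weights


def hz_to_boundary(f_hz: float, fs: float) -> float:
    """Convert a frequency in Hz to a normalized boundary in rad/sample.

    omega = 2*pi*f/fs, so 0 maps to 0 and the Nyquist frequency to pi.
    """
    if not 0 <= f_hz <= fs / 2:
        raise ValueError(f"frequency {f_hz} Hz outside [0, {fs / 2}] Hz")
    return 2.0 * np.pi * f_hz / fs


def _g(z: np.ndarray) -> np.ndarray:
    """Meyer transition polynomial: g(0)=0, g(1)=1, C^3 at both ends."""
    z = np.clip(z, 0.0, 1.0)
    return 35 * z**4 - 84 * z**5 + 70 * z**6 - 20 * z**7


def max_admissible_alpha(boundaries: np.ndarray) -> float:
    """Largest transition parameter keeping the bank a tight frame.

    With half-width eta_t = alpha * omega_t, neighbouring transitions must not
    overlap: alpha < min_t (omega_{t+1} - omega_t) / (omega_{t+1} + omega_t),
    taken over consecutive interior boundaries and the (last boundary, pi)
    pair.
    """
    pts = np.concatenate([boundaries, [np.pi]])
    ratios = (pts[1:] - pts[:-1]) / (pts[1:] + pts[:-1])
    return float(ratios.min())


@dataclass
class FilterBank:
    """Sampled EWT filter bank on the two-sided DFT grid of length ``n``.

    Attributes
    ----------
    responses : ndarray, shape (n, n_filters)
        Real frequency responses in [0, 1]; column 0 is the scaling (low-pass)
        filter, the rest are wavelet band-pass filters in ascending frequency.
    boundaries : ndarray
        Interior boundary points in rad/sample (excludes 0 and pi).
    alpha : float
        Transition-width parameter (eta_t = alpha * boundary_t).
    fs : float
        Sampling rate the boundaries were derived from.
    n : int
        DFT length the responses are sampled on.
    """

    responses: np.ndarray
    boundaries: np.ndarray
    alpha: float
    fs: float
    n: int

    @property
    def n_filters(self) -> int:
        return self.responses.shape[1]

    def band_edges_hz(self) -> list[tuple[float, float]]:
        """(low, high) edge in Hz of each filter's passband."""
        pts = np.concatenate([[0.0], self.boundaries, [np.pi]])
        hz = pts * self.fs / (2 * np.pi)
        return [(hz[i], hz[i + 1]) for i in range(len(hz) - 1)]


def build_filterbank(
    freqs_hz=DEFAULT_FREQS_HZ,
    fs: float = 512.0,
    n: int = 15360,
    alpha: float | str = "auto",
) -> FilterBank:
    """Construct the fixed-boundary empirical wavelet filter bank.

    Parameters
    ----------
    freqs_hz : sequence of float
        Strictly increasing boundary frequencies in (0, fs/2); the bank has
        ``len(freqs_hz) + 1`` filters.
    fs : float
        Sampling rate in Hz.
    n : int
        Frame length in samples (the DFT grid the filters are sampled on).
    alpha : float or "auto"
        Transition parameter; "auto" picks half the tight-frame bound.

    Returns
    -------
    FilterBank
        Filters satisfying the partition of unity sum_t H_t(w)^2 = 1.
    """
    freqs = np.asarray(freqs_hz, dtype=float)
    if freqs.ndim != 1 or freqs.size < 1:
        raise ValueError("need at least one boundary frequency")
    if not (np.all(np.diff(freqs) > 0) and freqs[0] > 0 and freqs[-1] < fs / 2):
        raise ValueError(
            "boundary frequencies must be strictly increasing within (0, fs/2)"
        )
    omega = np.array([hz_to_boundary(f, fs) for f in freqs])

    alpha_max = max_admissible_alpha(omega)
    if alpha == "auto":
        alpha_val = 0.5 * alpha_max
    else:
        alpha_val = float(alpha)
        if not 0 < alpha_val < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if alpha_val >= alpha_max:
            # name the offending pair for the error message
            pts = np.concatenate([omega, [np.pi]])
            ratios = (pts[1:] - pts[:-1]) / (pts[1:] + pts[:-1])
            t = int(np.argmin(ratios))
            raise ValueError(
                f"alpha={alpha_val:g} violates the tight-frame bound "
                f"{alpha_max:g} set by boundaries "
                f"({pts[t]:.4f}, {pts[t + 1]:.4f}) rad/sample"
            )

    eta = alpha_val * omega

    # two-sided DFT grid mapped to [0, pi] via |omega_k|
    k = np.arange(n)
    w = 2 * np.pi * k / n
    w = np.where(w > np.pi, 2 * np.pi - w, w)  # |omega| on (-pi, pi]

    n_filters = freqs.size + 1
    H = np.zeros((n, n_filters))

    def falling(x, b, e):
        """cos roll-off across [b-e, b+e]: 1 below, 0 above."""
        out = np.zeros_like(x)
        out[x <= b - e] = 1.0
        trans = (x > b - e) & (x < b + e)
        z = (x[trans] - (b - e)) / (2 * e)
        out[trans] = np.cos(np.pi / 2 * _g(z))
        return out

    def rising(x, b, e):
        """sin rise across [b-e, b+e]: 0 below, 1 above."""
        out = np.zeros_like(x)
        out[x >= b + e] = 1.0
        trans = (x > b - e) & (x < b + e)
        z = (x[trans] - (b - e)) / (2 * e)
        out[trans] = np.sin(np.pi / 2 * _g(z))
        return out

    # scaling filter: low-pass with roll-off at the first boundary
    H[:, 0] = falling(w, omega[0], eta[0])
    # wavelet filters: rise at boundary t-1, fall at boundary t
    for t in range(1, n_filters):
        lo = rising(w, omega[t - 1], eta[t - 1])
        if t < n_filters - 1:
            hi = falling(w, omega[t], eta[t])
        else:
            hi = np.ones_like(w)  # last band extends flat to Nyquist (pi)
        H[:, t] = lo * hi

    return FilterBank(responses=H, boundaries=omega, alpha=alpha_val, fs=fs, n=n)


def decompose(frame: MultichannelFrame, bank: FilterBank) -> np.ndarray:
    """Split every channel into the bank's sub-band modes.

    Mode t of channel c is Re{IDFT(DFT(x_c) * conj(H_t))}.

    Returns
    -------
    ndarray, shape (n_samples, n_channels, n_filters)
    """
    if frame.n_samples != bank.n:
        raise ValueError(
            f"frame has {frame.n_samples} samples but bank was built for {bank.n}"
        )
    spec = np.fft.fft(frame.data, axis=0)  # (n, m)
    # (n, m, 1) * (n, 1, T) -> (n, m, T); responses are real so conj is a no-op
    prod = spec[:, :, None] * np.conj(bank.responses)[:, None, :]
    modes = np.fft.ifft(prod, axis=0)
    return np.ascontiguousarray(modes.real)


def reconstruct(modes: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Synthesise the original frame from its mode tensor.

    The dual synthesis filters equal the analysis filters (tight frame), so
    the output matches the decomposed frame to floating-point accuracy.
    """
    if modes.shape[0] != bank.n or modes.shape[2] != bank.n_filters:
        raise ValueError("mode tensor does not match the filter bank")
    spec = np.fft.fft(modes, axis=0)  # (n, m, T)
    out = np.fft.ifft((spec * bank.responses[:, None, :]).sum(axis=2), axis=0)
    return out.real


def band_energy_fractions(modes: np.ndarray) -> np.ndarray:
    """Fraction of total energy in each mode, per channel.

    Returns shape (n_channels, n_filters); rows sum to 1 for non-silent
    channels.
    """
    energy = (modes**2).sum(axis=0)  # (m, T)
    total = energy.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, energy / total, 0.0)
    return frac
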