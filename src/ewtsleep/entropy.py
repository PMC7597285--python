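"""Dispersion and bubble entropy of sub-band signals, and the feature vector.

Dispersion entropy (DE) maps a signal through the normal CDF of its own mean
and standard deviation, quantizes the mapped values into ``a`` levels, embeds
the level series into length-``L`` delay vectors, and takes the Shannon
entropy of the resulting dispersion-pattern distribution.  It is bounded by
[0, L*ln(a)] and invariant to positive affine rescaling of the input.

Bubble entropy (BE) embeds the raw signal, counts the bubble-sort swaps
(inversions) needed to sort each delay vector ascending, histograms the swap
counts, and reports the growth of the order-2 Renyi entropy of that histogram
from embedding dimension L to L+1, normalized by ln((L+1)/(L-1)).  It depends
only on the ranks of the samples, so it is invariant to any strictly
increasing transform.

Both are computed per rhythm sub-band per channel; for a 4-channel frame and
the five classical rhythms this yields the 40-dimensional feature vector
(20 DE + 20 BE) used by the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import norm


@dataclass(frozen=True)
class EntropyParams:
    """Embedding parameters: length L, delay d, and (DE only) level count a."""

    L: int = 10
    d: int = 1
    a: int = 2

    def __post_init__(self) -> None:
        if self.L < 2 or self.d < 1 or self.a < 2:
            raise ValueError("require L >= 2, d >= 1, a >= 2")


DEFAULT_DE_PARAMS = EntropyParams(L=10, d=1, a=2)
DEFAULT_BE_L = 10
DEFAULT_BE_D = 1


def ncdf_map(x: np.ndarray) -> np.ndarray:
    """Map a signal into (0, 1) via the normal CDF of its own mean/sd.

    A constant signal (sd = 0) maps to all 0.5.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("signal is empty")
    mu = x.mean()
    sigma = x.std()
    if sigma == 0:
        return np.full_like(x, 0.5)
    return norm.cdf((x - mu) / sigma)


def quantize_levels(y: np.ndarray, a: int) -> np.ndarray:
    """Assign each mapped sample a level in {1, .., a}.

    z = round(a*y + 0.5) with half-away-from-zero rounding, clipped to [1, a].
    """
    v = a * np.asarray(y, dtype=float) + 0.5
    z = np.floor(v + 0.5).astype(np.int64)  # half-away-from-zero for v > 0
    return np.clip(z, 1, a)


def _embed(x: np.ndarray, L: int, d: int) -> np.ndarray:
    """Delay-embedding matrix of shape (N - (L-1)d, L)."""
    x = np.asarray(x)
    n_vec = x.size - (L - 1) * d
    if n_vec < 1:
        raise ValueError(
            f"signal of length {x.size} too short for L={L}, d={d}; "
            f"need at least {(L - 1) * d + 1} samples"
        )
    return sliding_window_view(x, (L - 1) * d + 1)[:, ::d]


def dispersion_entropy(x: np.ndarray, params: EntropyParams = DEFAULT_DE_PARAMS) -> float:
    """Dispersion entropy in nats.

    Pipeline: NCDF map -> level quantization -> delay embedding -> Shannon
    entropy of the dispersion-pattern relative frequencies.
    """
    z = quantize_levels(ncdf_map(x), params.a)
    vecs = _embed(z, params.L, params.d)
    # encode each pattern as a base-a integer for O(n) counting
    powers = params.a ** np.arange(params.L, dtype=np.int64)
    codes = (vecs - 1) @ powers
    _, counts = np.unique(codes, return_counts=True)
    p = counts / vecs.shape[0]
    return float(-(p * np.log(p)).sum())


def count_swaps(v: np.ndarray) -> int:
    """Number of bubble-sort exchanges to sort ``v`` ascending (= inversions).

    Equal-valued pairs are not inversions: a stable ascending sort never
    swaps them.
    """
    v = np.asarray(v)
    i, j = np.triu_indices(v.size, k=1)
    return int(np.count_nonzero(v[i] > v[j]))


def _swap_counts(vecs: np.ndarray) -> np.ndarray:
    """Inversion count of every row of an embedding matrix (vectorized)."""
    k = vecs.shape[1]
    i, j = np.triu_indices(k, k=1)
    return (vecs[:, i] > vecs[:, j]).sum(axis=1)


def swap_histogram(x: np.ndarray, k: int, d: int = 1) -> np.ndarray:
    """Probabilities over achievable swap counts 0 .. k(k-1)/2 at dimension k."""
    vecs = _embed(np.asarray(x, dtype=float), k, d)
    swaps = _swap_counts(vecs)
    n_bins = k * (k - 1) // 2 + 1
    counts = np.bincount(swaps, minlength=n_bins)
    return counts / vecs.shape[0]


def renyi2(p: np.ndarray) -> float:
    """Order-2 Renyi entropy -ln(sum p^2) of a normalized histogram."""
    p = np.asarray(p, dtype=float)
    s = float((p**2).sum())
    if s <= 0:
        raise ValueError("histogram has no mass")
    return -np.log(s)


def bubble_entropy(x: np.ndarray, L: int = DEFAULT_BE_L, d: int = DEFAULT_BE_D) -> float:
    """Bubble entropy: normalized Renyi-entropy growth from dimension L to L+1.

    BE = (E_{L+1} - E_L) / ln((L+1)/(L-1)) where E_k is the order-2 Renyi
    entropy of the swap-count histogram at embedding dimension k.
    """
    if L < 2:
        raise ValueError("bubble entropy needs L >= 2")
    e_lo = renyi2(swap_histogram(x, L, d))
    e_hi = renyi2(swap_histogram(x, L + 1, d))
    return float((e_hi - e_lo) / np.log((L + 1) / (L - 1)))


def extract_features(
    modes: np.ndarray,
    de_params: EntropyParams = DEFAULT_DE_PARAMS,
    be_L: int = DEFAULT_BE_L,
    be_d: int = DEFAULT_BE_D,
    bands: tuple[int, ...] = (0, 1, 2, 3, 4),
) -> np.ndarray:
    """Entropy feature vector of a decomposed frame.

    Parameters
    ----------
    modes : ndarray, shape (n_samples, n_channels, n_modes)
        Output of :func:`ewtsleep.filterbank.decompose`.
    bands : tuple of int
        Mode indices to featurize; the default keeps the five classical
        rhythms (delta..gamma) and drops the residual high band.

    Returns
    -------
    ndarray of length 2 * n_channels * len(bands): all DE values first, then
    all BE values, each block ordered channel-major then band.
    """
    if modes.ndim != 3:
        raise ValueError("expected a samples x channels x modes tensor")
    if max(bands) >= modes.shape[2]:
        raise ValueError(
            f"band index {max(bands)} out of range for {modes.shape[2]} modes"
        )
    de, be = [], []
    for c in range(modes.shape[1]):
        for b in bands:
            sub = modes[:, c, b]
            de_val = dispersion_entropy(sub, de_params)
            be_val = bubble_entropy(sub, be_L, be_d)
            if not (np.isfinite(de_val) and np.isfinite(be_val)):
                raise ValueError(
                    f"non-finite entropy for channel {c}, band {b}"
                )
            de.append(de_val)
            be.append(be_val)
    return np.array(de + be)


def feature_names(
    channels: list[str],
    bands: tuple[int, ...] = (0, 1, 2, 3, 4),
    band_labels: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma", "high"),
) -> list[str]:
    """Column names matching :func:`extract_features` ordering."""
    names = []
    for kind in ("DE", "BE"):
        for ch in channels:
            for b in bands:
                names.append(f"{kind}_{ch}_{band_labels[b]}")
    return names
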