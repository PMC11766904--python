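"""Discrete Fourier transforms for spectrogram construction.

The pipeline turns each 30 s EEG epoch into a channel-by-frequency amplitude
image, so it needs an exact-length DFT (no zero padding: a 15000-sample epoch
at 500 Hz must yield a bin spacing of exactly 1/30 Hz).  Two routes are
provided:

* :func:`dft_direct` — the O(N^2) definition, evaluated literally.  It is the
  oracle the fast path is tested against.
* :func:`fft` — a decimation-in-time Cooley–Tukey transform.  Power-of-two
  lengths use the classic radix-2 even/odd split; composite lengths split by
  their smallest prime factor; large prime lengths fall back to Bluestein's
  chirp-z algorithm (which itself only needs power-of-two transforms).

Both accept real or complex input and agree to ~1e-12 relative error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Spectrum", "dft_direct", "fft", "fft_many", "amplitude_spectrum"]

# Direct small-prime DFT is cheaper than Bluestein below this length.
_SMALL_PRIME_DIRECT = 64


@dataclass(frozen=True)
class Spectrum:
    """DFT coefficients of a single channel.

    Attributes
    ----------
    coefficients : complex ndarray, shape (n,)
        ``X_k`` for ``k = 0 … n-1``.
    n : int
        Transform length.
    fs : float
        Sampling rate in Hz of the originating signal.
    """

    coefficients: np.ndarray
    n: int
    fs: float

    @property
    def df(self) -> float:
        """Bin spacing in Hz, ``fs / n``."""
        return self.fs / self.n

    @property
    def freqs(self) -> np.ndarray:
        """Frequency of every bin, ``k * fs / n``."""
        return np.arange(self.n) * (self.fs / self.n)


def dft_direct(x: np.ndarray, fs: float = 1.0, _block: int = 256) -> Spectrum:
    """Evaluate ``X_k = sum_m x_m exp(-2πi k m / N)`` literally, in O(N^2).

    Serves as the independent oracle for :func:`fft`.  Evaluated blockwise in
    k so the exponent matrix never exceeds ``_block × N`` entries.
    """
    x = np.asarray(x)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("dft_direct expects a non-empty 1-D array")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    n = x.size
    m = np.arange(n)
    out = np.empty(n, dtype=np.complex128)
    xc = x.astype(np.complex128)
    for start in range(0, n, _block):
        k = np.arange(start, min(start + _block, n))
        out[k] = np.exp(-2j * np.pi * np.outer(k, m) / n) @ xc
    return Spectrum(out, n, float(fs))


def _smallest_prime_factor(n: int) -> int:
    if n % 2 == 0:
        return 2
    p = 3
    while p * p <= n:
        if n % p == 0:
            return p
        p += 2
    return n


def _dft_matrix_lastaxis(x: np.ndarray) -> np.ndarray:
    n = x.shape[-1]
    km = np.outer(np.arange(n), np.arange(n))
    return x @ np.exp(-2j * np.pi * km / n)


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def _bluestein_lastaxis(x: np.ndarray) -> np.ndarray:
    """Chirp-z route for prime lengths: re-expresses the DFT as a linear
    convolution, which is carried out with power-of-two transforms only."""
    n = x.shape[-1]
    k = np.arange(n)
    chirp = np.exp(-1j * np.pi * (k * k % (2 * n)) / n)  # exact phase mod 2N
    m = _next_pow2(2 * n - 1)
    a = np.zeros(x.shape[:-1] + (m,), dtype=np.complex128)
    a[..., :n] = x * chirp
    b = np.zeros(m, dtype=np.complex128)
    b[:n] = np.conj(chirp)
    b[m - n + 1 :] = np.conj(chirp[1:][::-1])
    conv = _ifft_pow2(_fft_lastaxis(a) * _fft_lastaxis(b))
    return conv[..., :n] * chirp


def _ifft_pow2(x: np.ndarray) -> np.ndarray:
    n = x.shape[-1]
    return np.conj(_fft_lastaxis(np.conj(x))) / n


def _fft_lastaxis(x: np.ndarray) -> np.ndarray:
    """Decimation-in-time Cooley–Tukey over the last axis.

    For length N = p·m (p the smallest prime factor) the input is split into p
    interleaved subsequences whose length-m DFTs ``E_j`` combine as

        X_k = Σ_j exp(-2πi j k / N) · E_j[k mod m].

    With p = 2 this is exactly the textbook even/odd recursion
    ``X_k = E_k + exp(-2πi k / N) O_k``.  Every recursion level operates on
    the whole batch at once, so Python-level depth is only the number of
    prime factors of N.
    """
    n = x.shape[-1]
    if n == 1:
        return x.astype(np.complex128)
    p = _smallest_prime_factor(n)
    if p == n:  # prime length: direct matrix if small, Bluestein otherwise
        if n <= _SMALL_PRIME_DIRECT:
            return _dft_matrix_lastaxis(x.astype(np.complex128))
        return _bluestein_lastaxis(x.astype(np.complex128))
    m = n // p
    # x.reshape(..., m, p)[..., t, j] == x[..., t*p + j]  →  axis -1 indexes
    # the p interleaved subsequences after the swap.
    sub = np.swapaxes(x.reshape(x.shape[:-1] + (m, p)), -1, -2)
    e = _fft_lastaxis(sub)  # (..., p, m)
    k = np.arange(n)
    j = np.arange(p)
    twiddle = np.exp(-2j * np.pi * np.multiply.outer(j, k) / n)  # (p, n)
    # Split k as i*m + r: X[..., i*m + r] = Σ_j twiddle[j, i*m + r] E_j[r]
    # (E_j[k mod m] tiles across the p output blocks).
    tw = twiddle.reshape(p, p, m)
    out = np.einsum("jim,...jm->...im", tw, e, optimize=True)
    return out.reshape(x.shape[:-1] + (n,))


def fft(x: np.ndarray, fs: float = 1.0) -> Spectrum:
    """Cooley–Tukey DFT of a 1-D signal; contract-identical to dft_direct."""
    x = np.asarray(x)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("fft expects a non-empty 1-D array")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    return Spectrum(_fft_lastaxis(x), x.size, float(fs))


def fft_many(x: np.ndarray, fs: float = 1.0) -> np.ndarray:
    """Batched transform over the last axis (channels × samples → channels ×
    coefficients).  Same algorithm as :func:`fft`; used for whole epochs."""
    x = np.asarray(x)
    if x.ndim < 1 or x.shape[-1] == 0:
        raise ValueError("fft_many expects at least one sample per row")
    return _fft_lastaxis(x)


def amplitude_spectrum(spec: Spectrum) -> np.ndarray:
    """Single-sided amplitude in input units (µV for EEG).

    ``a_0 = |X_0|/N``; ``a_k = 2|X_k|/N`` for ``0 < k < N/2``; the Nyquist bin
    (even N) carries no conjugate partner so ``a_{N/2} = |X_{N/2}|/N``.
    A pure sinusoid of amplitude A landing on a bin reads back as A.
    """
    n = spec.n
    half = n // 2 + 1
    a = np.abs(spec.coefficients[:half]) / n
    if n > 1:
        last = half - 1 if n % 2 == 0 else half
        a[1:last] *= 2.0
    return a
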