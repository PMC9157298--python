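"""Band-limited Gaussian signal primitives used by the generators.

Signals are synthesised in the frequency domain: white Gaussian noise is
shaped by a hard spectral mask over the requested band, which makes the
output exactly band-limited and keeps phase-lag constructions analytic.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from .config import BandSpec


def band_limited_noise(n_samples: int, sampling_rate: float, band: BandSpec,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with support strictly inside `band`."""
    if band.high >= sampling_rate / 2.0:
        raise ValueError("band exceeds Nyquist")
    spec = rng.standard_normal(n_samples) + 1j * rng.standard_normal(n_samples)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    mask = (freqs >= band.low) & (freqs <= band.high)
    shaped = spec[: freqs.size] * mask
    x = np.fft.irfft(shaped, n=n_samples)
    sd = x.std()
    if sd == 0.0:  # degenerate: no FFT bin inside the band
        raise ValueError("band too narrow for the requested signal length")
    return x / sd


def phase_rotate(x: np.ndarray, lag: float) -> np.ndarray:
    """Rotate every spectral component of a band-limited signal by `lag` rad.

    For a signal without DC content this realises an exact constant phase
    shift: the analytic signal is multiplied by ``exp(-1j * lag)`` and the
    real part taken, so the rotated signal trails `x` by `lag` radians at
    every in-band frequency.
    """
    return np.real(hilbert(x) * np.exp(-1j * lag))


def analytic(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Analytic signal (Hilbert transform) along `axis`."""
    return hilbert(x, axis=axis)
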