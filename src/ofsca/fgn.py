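"""Exact simulation of fractional Gaussian noise and fractional Brownian motion.

Fractional Gaussian noise (fGn) is the stationary increment process of
fractional Brownian motion (fBm).  For Hurst exponent ``H`` in (0, 1) the
autocovariance of unit-variance fGn is

    gamma(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}),

persistent for H > 1/2, white for H = 1/2 and anti-persistent for H < 1/2.
Sampling uses circulant embedding (Davies-Harte): the covariance is embedded
in a circulant matrix diagonalised by the FFT, so the generated series carries
the *exact* target covariance rather than a spectral approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FgnSeries",
    "fgn_autocovariance",
    "generate_fgn",
    "integrate_to_fbm",
    "generate_fbm",
]


@dataclass(frozen=True)
class FgnSeries:
    """A sampled fractional Gaussian noise series with its Hurst exponent."""

    values: np.ndarray
    hurst: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not 0.0 < self.hurst < 1.0:
            raise ValueError(f"hurst must lie strictly in (0, 1), got {self.hurst}")
        if values.ndim != 1 or values.size < 2:
            raise ValueError("values must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return self.values.size


def fgn_autocovariance(lags: np.ndarray | int, hurst: float) -> np.ndarray:
    """Closed-form autocovariance gamma(k) of unit-variance fGn."""
    k = np.abs(np.atleast_1d(np.asarray(lags, dtype=float)))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1.0) ** h2 - 2.0 * k ** h2 + np.abs(k - 1.0) ** h2)


def generate_fgn(
    n: int,
    hurst: float,
    seed: int | np.random.Generator | None = None,
) -> FgnSeries:
    """Draw an exact, zero-mean, unit-variance fGn sample of length ``n``.

    Parameters
    ----------
    n : int
        Series length, at least 2.
    hurst : float
        Hurst exponent, strictly inside (0, 1).
    seed : int, numpy Generator or None
        Source of randomness; identical seeds give identical series.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must lie strictly in (0, 1), got {hurst}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed)

    gamma = fgn_autocovariance(np.arange(n), hurst)
    # first row of the minimal circulant embedding, size m = 2n - 2
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    m = row.size
    lam = np.fft.rfft(row).real
    neg = lam < 0.0
    if np.any(neg):
        # The embedding is nonnegative definite for fGn in theory; tiny
        # negative eigenvalues can appear from roundoff and are clipped.
        if lam.min() < -1e-8 * lam.max():
            warnings.warn(
                "circulant embedding produced significant negative eigenvalues; "
                "clipping them biases the covariance slightly",
                RuntimeWarning,
                stacklevel=2,
            )
        lam = np.clip(lam, 0.0, None)

    # Hermitian complex normals xi_k with E|xi_k|^2 = 1; endpoints real.
    z = rng.standard_normal(lam.size) + 1j * rng.standard_normal(lam.size)
    z[0] = z[0].real * np.sqrt(2.0)
    z[-1] = z[-1].real * np.sqrt(2.0)
    spectrum = z * np.sqrt(lam * m / 2.0)
    values = np.fft.irfft(spectrum, n=m)[:n]
    return FgnSeries(values=values, hurst=hurst)


def integrate_to_fbm(noise: FgnSeries | np.ndarray) -> np.ndarray:
    """Cumulative sum of fGn increments, i.e. a fractional Brownian path."""
    values = noise.values if isinstance(noise, FgnSeries) else np.asarray(noise, float)
    if values.size == 0:
        raise ValueError("cannot integrate an empty series")
    return np.cumsum(values)


def generate_fbm(
    n: int,
    hurst: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Convenience wrapper: exact fGn sample integrated to an fBm path."""
    return integrate_to_fbm(generate_fgn(n, hurst, seed))
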