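"""Rician magnitude noise: generation and background-based level estimation.

Magnitude MR images are Rician distributed: a noise-free signal ``S`` observed
through two independent Gaussian channels of SD ``sigma`` becomes
``M = sqrt((S + n1)^2 + n2^2)``.  Signal-free background is then Rayleigh, with
mean ``sigma * sqrt(pi/2)`` and SD ``sigma * sqrt(2 - pi/2)``; the second
moment satisfies ``E[M^2] = S^2 + 2 sigma^2``, which is the identity the
Rician-corrected non-local means filter relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RAYLEIGH_SD_FACTOR, CineSeries, logger

BACKGROUND_SD_RAYLEIGH = "background_sd_rayleigh"
BACKGROUND_SD_RAW = "background_sd_raw"


@dataclass(frozen=True)
class NoiseEstimate:
    """Estimated noise level.

    ``sigma`` is the Gaussian channel SD for the Rayleigh-corrected method and
    the raw background SD otherwise; ``n_voxels`` is the number of background
    voxels used.
    """

    sigma: float
    method: str
    n_voxels: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_voxels < 2:
            raise ValueError("need at least 2 voxels for an SD")


def rician_sample(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one Rician-noised realization of a noise-free magnitude array."""
    signal = np.asarray(signal, dtype=np.float64)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return signal.copy()
    n1 = rng.normal(scale=sigma, size=signal.shape)
    n2 = rng.normal(scale=sigma, size=signal.shape)
    return np.hypot(signal + n1, n2)


def add_rician_noise(series: CineSeries, sigma: float, seed: int) -> CineSeries:
    """Corrupt a cine series with Rician noise of Gaussian-channel SD ``sigma``.

    The random stream is derived from ``seed`` and split per cardiac phase, so
    a single phase can be re-noised reproducibly without generating the rest of
    the series.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return series.with_data(series.data.astype(np.float64).copy())
    children = np.random.SeedSequence(seed).spawn(series.n_phases)
    out = np.empty(series.data.shape, dtype=np.float64)
    for p in range(series.n_phases):
        rng = np.random.default_rng(children[p])
        out[:, :, :, p] = rician_sample(series.phase(p), sigma, rng)
    return series.with_data(out)


def phase_noise_rng(seed: int, n_phases: int, p: int) -> np.random.Generator:
    """The per-phase generator used by :func:`add_rician_noise` (stream ``p``)."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(n_phases)[p])


def estimate_sigma(
    volume: np.ndarray,
    background_mask: np.ndarray,
    method: str = BACKGROUND_SD_RAYLEIGH,
) -> NoiseEstimate:
    """Estimate the noise level from signal-free background voxels.

    The default ``background_sd_rayleigh`` divides the background SD by
    ``sqrt(2 - pi/2)``, returning the Gaussian-channel sigma implied by
    Rayleigh statistics (what the Rician bias correction needs).
    ``background_sd_raw`` returns the uncorrected background SD (the quantity
    the SNR definition divides by).
    """
    volume = np.asarray(volume, dtype=np.float64)
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != volume.shape:
        if volume.ndim == 3 and background_mask.shape == volume.shape[:2]:
            background_mask = np.broadcast_to(background_mask[:, :, None], volume.shape)
        else:
            raise ValueError(
                f"mask shape {background_mask.shape} incompatible with volume shape {volume.shape}"
            )
    values = volume[background_mask]
    if values.size < 2:
        raise ValueError("background mask selects fewer than 2 voxels")
    if values.size < 100:
        logger.warning("background mask selects only %d voxels (< 100); estimate is noisy", values.size)
    sd = float(values.std(ddof=1))
    mean = float(values.mean())
    if sd > 0:
        ratio = mean / sd
        if not (1.2 <= ratio <= 4.0):
            logger.warning(
                "background mean/SD = %.3f is outside [1.2, 4.0]; background may not be "
                "signal-free Rayleigh noise",
                ratio,
            )
    if method == BACKGROUND_SD_RAYLEIGH:
        sigma = sd / RAYLEIGH_SD_FACTOR
    elif method == BACKGROUND_SD_RAW:
        sigma = sd
    else:
        raise ValueError(
            f"unknown method {method!r}; expected {BACKGROUND_SD_RAYLEIGH!r} or {BACKGROUND_SD_RAW!r}"
        )
    return NoiseEstimate(sigma=sigma, method=method, n_voxels=int(values.size))


def default_background_roi(volume: np.ndarray, size: int = 24) -> np.ndarray:
    """Rectangular background mask in the bottom-right in-plane corner.

    Covers ``size x size`` voxels at the high-index corner of the first two
    (in-plane) axes, on every slice of a 3D volume.  The corner is the region
    the imaging protocol leaves outside the animal.
    """
    volume = np.asarray(volume)
    if volume.ndim not in (2, 3):
        raise ValueError("volume must be a 2D slice or a 3D volume")
    nx, ny = volume.shape[:2]
    if nx < 32 or ny < 32:
        raise ValueError(f"in-plane matrix {nx}x{ny} too small (need >= 32 in each dimension)")
    size = int(size)
    if not (0 < size <= min(nx, ny)):
        raise ValueError("background ROI size must be positive and fit in the image")
    mask = np.zeros(volume.shape, dtype=bool)
    mask[nx - size:, ny - size:, ...] = True
    return mask
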