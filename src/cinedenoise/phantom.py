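"""Synthetic left-ventricle cine phantom and simulated human observers.

The phantom replaces an undeposited small-animal acquisition: a short-axis
stack in which the ventricular cavity is a column of bright discs whose radius
follows a raised-cosine contraction between end-diastole (phase 0) and
end-systole (mid cycle), wrapped in a grey myocardial annulus whose total
volume is held constant across phases (the wall thickens as the cavity
contracts).  Ground-truth masks and cardiac-function parameters come for free,
standing in for the ex-vivo gold standard.

Manual segmentation is emulated by :func:`simulate_observer`, which displaces
the endocardial and epicardial contours radially by a systematic bias plus
smooth zero-mean angular noise, then re-rasterizes labels.  The jitter scale is
meant to be tied to image contrast via :func:`cnr_linked_jitter`: crisper
(better denoised) images give tighter contours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    LABEL_BACKGROUND,
    LABEL_CAVITY,
    LABEL_MYOCARDIUM,
    CineSeries,
    SegmentationSet,
    logger,
)
from .function import CardiacFunction, compute_function

#: angular harmonics of the observer contour-noise field (plus a DC term)
_N_HARMONICS = 3
#: angular bins used to extract and re-rasterize contours
_N_ANGLE_BINS = 64


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and contrast of the synthetic acquisition.

    Defaults emulate the study protocol: 256 x 256 matrix at 0.195 mm in-plane,
    15 slices of 1 mm, 16 cardiac phases, bright blood over grey myocardium.
    ``r_ed``/``r_es`` are the cavity radii (mm) at end-diastole/end-systole and
    ``myo_volume`` the myocardial volume (mm^3) conserved across phases.
    """

    nx: int = 256
    ny: int = 256
    n_slices: int = 15
    n_phases: int = 16
    dx: float = 0.195
    dy: float = 0.195
    dz: float = 1.0
    r_ed: float = 4.5
    r_es: float = 2.46
    myo_volume: float = 700.0
    i_blood: float = 2.0
    i_myo: float = 1.0
    base_slice: int = 3
    apex_slice: int = 12

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.n_slices) < 1 or self.n_phases < 1:
            raise ValueError("grid dimensions and phase count must be positive")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel spacings must be positive")
        if not (self.r_ed >= self.r_es > 0):
            raise ValueError("need r_ed >= r_es > 0")
        if not (self.i_blood > self.i_myo > 0):
            raise ValueError("need i_blood > i_myo > 0")
        if not (0 <= self.base_slice <= self.apex_slice < self.n_slices):
            raise ValueError("need 0 <= base_slice <= apex_slice < n_slices")
        if self.myo_volume <= 0:
            raise ValueError("myo_volume must be positive")

    @property
    def n_ventricle_slices(self) -> int:
        return self.apex_slice - self.base_slice + 1


@dataclass(frozen=True)
class ObserverModel:
    """A simulated observer: systematic radial bias plus smooth contour jitter.

    ``jitter_scale`` is the pointwise SD (voxels) of the zero-mean radial
    displacement noise; ``dilation_bias`` a signed constant shift (voxels,
    positive = outward) applied to both contours.
    """

    jitter_scale: float
    dilation_bias: float
    seed: int

    def __post_init__(self) -> None:
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth bundled with a generated phantom.

    ``sigma`` is the injected noise level; it is 0 on generation and filled in
    by the study driver once the noise level has been calibrated.
    """

    truth_seg: SegmentationSet
    true_function: CardiacFunction
    config: PhantomConfig
    sigma: float = 0.0


def cavity_radius(config: PhantomConfig, phase: int) -> float:
    """Cavity radius (mm) at ``phase``: raised cosine, ED at 0, ES at mid cycle."""
    frac = (1.0 + math.cos(2.0 * math.pi * phase / config.n_phases)) / 2.0
    return config.r_es + (config.r_ed - config.r_es) * frac


def epicardial_radius(config: PhantomConfig, phase: int) -> float:
    """Outer myocardial radius (mm) keeping total wall volume at ``myo_volume``."""
    r = cavity_radius(config, phase)
    area = config.myo_volume / (config.dz * config.n_ventricle_slices)
    return math.sqrt(area / math.pi + r * r)


def generate_phantom(config: PhantomConfig) -> tuple[CineSeries, PhantomTruth]:
    """Build the noise-free cine series and its ground truth.

    Deterministic: the phantom has no randomness.  Raises if the epicardial
    annulus of any phase would reach the edge of the grid.
    """
    half_x = config.nx * config.dx / 2.0
    half_y = config.ny * config.dy / 2.0
    margin = max(config.dx, config.dy)
    xc = (np.arange(config.nx) - (config.nx - 1) / 2.0) * config.dx
    yc = (np.arange(config.ny) - (config.ny - 1) / 2.0) * config.dy
    rho = np.hypot(xc[:, None], yc[None, :])

    labels = np.zeros((config.nx, config.ny, config.n_slices, config.n_phases), dtype=np.uint8)
    for p in range(config.n_phases):
        r = cavity_radius(config, p)
        r_epi = epicardial_radius(config, p)
        if r_epi + margin > min(half_x, half_y):
            raise ValueError(
                f"phase {p}: epicardial radius {r_epi:.2f} mm does not fit the "
                f"{config.nx}x{config.ny} grid at {config.dx:.3f} mm spacing"
            )
        slice_labels = np.full((config.nx, config.ny), LABEL_BACKGROUND, dtype=np.uint8)
        slice_labels[rho < r] = LABEL_CAVITY
        slice_labels[(rho >= r) & (rho < r_epi)] = LABEL_MYOCARDIUM
        labels[:, :, config.base_slice : config.apex_slice + 1, p] = slice_labels[:, :, None]

    intensity = np.zeros(labels.shape, dtype=np.float64)
    intensity[labels == LABEL_CAVITY] = config.i_blood
    intensity[labels == LABEL_MYOCARDIUM] = config.i_myo

    spacing = (config.dx, config.dy, config.dz)
    series = CineSeries(data=intensity, spacing=spacing)
    truth_seg = SegmentationSet(labels=labels, spacing=spacing)
    true_function = compute_function(truth_seg)
    return series, PhantomTruth(truth_seg=truth_seg, true_function=true_function, config=config)


def cnr_linked_jitter(cnr: float, c: float) -> float:
    """Observer jitter scale (voxels) as ``c / cnr``.

    Encodes that better tissue contrast yields tighter manual contours; with
    the same constant ``c`` across conditions, the noisiest (raw) images get
    the largest contour jitter.
    """
    if cnr <= 0:
        raise ValueError("cnr must be positive")
    if c <= 0:
        raise ValueError("c must be positive")
    return c / cnr


def _smooth_angular_noise(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance smooth periodic field: DC term + 3 Fourier harmonics.

    Coefficient variances sum to 1 pointwise, a quarter of it in the DC term so
    that a contour can be systematically too large/small on a given slice.
    """
    scale = 0.5  # each of the 4 variance shares is 0.25
    g = np.full(theta.shape, rng.normal(scale=scale))
    for k in range(1, _N_HARMONICS + 1):
        a = rng.normal(scale=scale / math.sqrt(2.0))
        b = rng.normal(scale=scale / math.sqrt(2.0))
        g = g + a * np.cos(k * theta) + b * np.sin(k * theta)
    return g


def _bin_thresholds(inside: np.ndarray, rho: np.ndarray, bins: np.ndarray) -> np.ndarray:
    """Per-angular-bin boundary radius separating ``inside`` from the rest.

    Uses the midpoint between the outermost inside voxel and the innermost
    outside voxel of each bin, so that re-rasterizing with a zero displacement
    reproduces the input set exactly (for radially ordered masks).
    """
    r_in = np.full(_N_ANGLE_BINS, -np.inf)
    np.maximum.at(r_in, bins[inside], rho[inside])
    r_out = np.full(_N_ANGLE_BINS, np.inf)
    outside = ~inside
    np.minimum.at(r_out, bins[outside], rho[outside])
    # every bin of a full 2D slice contains voxels, so r_out is always finite
    return np.where(np.isfinite(r_in), (r_in + r_out) / 2.0, r_out - 1e-3)


def simulate_observer(truth: SegmentationSet, model: ObserverModel) -> SegmentationSet:
    """Produce one imperfect manual segmentation of ``truth``.

    Each slice's endocardial and epicardial contours are displaced radially by
    ``dilation_bias`` plus smooth zero-mean noise of SD ``jitter_scale``
    (independent fields per contour and per slice), then labels are
    re-rasterized.  Displacements are in voxel units of the in-plane grid.
    Bit-reproducible given ``model.seed``; with zero bias and jitter the output
    equals the input exactly.
    """
    rng = np.random.default_rng(model.seed)
    labels = truth.labels
    nx, ny, nz, n_phases = labels.shape
    out = labels.copy()

    ix, iy = np.indices((nx, ny))
    clamped = False
    for p in range(n_phases):
        for z in range(nz):
            sl = labels[:, :, z, p]
            tissue = sl != LABEL_BACKGROUND
            if not tissue.any():
                continue
            cavity = sl == LABEL_CAVITY
            centre_src = cavity if cavity.any() else tissue
            cx = ix[centre_src].mean()
            cy = iy[centre_src].mean()
            ddx = ix - cx
            ddy = iy - cy
            rho = np.hypot(ddx, ddy)
            theta = np.arctan2(ddy, ddx)
            bins = np.clip(
                ((theta + math.pi) / (2.0 * math.pi) * _N_ANGLE_BINS).astype(np.intp),
                0,
                _N_ANGLE_BINS - 1,
            )
            base_endo = _bin_thresholds(cavity, rho, bins)
            base_epi = _bin_thresholds(tissue, rho, bins)
            delta_endo = model.dilation_bias + model.jitter_scale * _smooth_angular_noise(theta, rng)
            delta_epi = model.dilation_bias + model.jitter_scale * _smooth_angular_noise(theta, rng)
            r_endo = np.maximum(base_endo[bins] + delta_endo, 0.0)
            r_epi = base_epi[bins] + delta_epi
            bad = r_epi < r_endo
            if bad.any():
                clamped = True
                r_epi = np.maximum(r_epi, r_endo)
            new = np.full((nx, ny), LABEL_BACKGROUND, dtype=np.uint8)
            new[rho < r_endo] = LABEL_CAVITY
            new[(rho >= r_endo) & (rho < r_epi)] = LABEL_MYOCARDIUM
            out[:, :, z, p] = new
    if clamped:
        logger.warning(
            "simulate_observer: epicardial contour crossed the endocardial contour on "
            "at least one slice; displacement clamped"
        )
    return SegmentationSet(labels=out, spacing=truth.spacing)
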