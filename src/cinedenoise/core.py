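"""Shared containers and physical constants for the cine-MRI pipeline.

A cine acquisition is stored as a 4D magnitude array indexed ``(x, y, slice,
phase)`` together with its voxel spacing in millimetres.  Label maps use the
codes 0 = background, 1 = ventricular cavity (blood pool), 2 = myocardium.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

logger = logging.getLogger("cinedenoise")

#: label codes shared by every module
LABEL_BACKGROUND = 0
LABEL_CAVITY = 1
LABEL_MYOCARDIUM = 2

#: myocardial tissue density used to convert segmented volume to mass
MYOCARDIAL_DENSITY_G_PER_CM3 = 1.05

#: SD of a Rayleigh variate with Gaussian channel sigma = 1:  sqrt(2 - pi/2)
RAYLEIGH_SD_FACTOR = math.sqrt(2.0 - math.pi / 2.0)
#: mean of a Rayleigh variate with Gaussian channel sigma = 1:  sqrt(pi/2)
RAYLEIGH_MEAN_FACTOR = math.sqrt(math.pi / 2.0)

Spacing = Tuple[float, float, float]


def _check_spacing(spacing: Spacing) -> Tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)  # type: ignore[assignment]
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths (mm), got {spacing!r}")
    return spacing  # type: ignore[return-value]


@dataclass
class CineSeries:
    """4D magnitude cine series, one 3D volume per cardiac phase.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, n_slices, n_phases)``, non-negative
        (magnitude image), arbitrary intensity units.
    spacing:
        Voxel size ``(dx, dy, dz)`` in mm.
    """

    data: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"cine series must be 4D (x, y, slice, phase), got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cine series contains non-finite intensities")
        if np.any(self.data < 0):
            raise ValueError("magnitude image must be non-negative everywhere")
        self.spacing = _check_spacing(self.spacing)

    @property
    def n_phases(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_volume_ul(self) -> float:
        """Volume of one voxel in mm^3 (= microlitres)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def phase(self, p: int) -> np.ndarray:
        """The 3D volume of cardiac phase ``p`` (a view)."""
        return self.data[:, :, :, p]

    def with_data(self, data: np.ndarray) -> "CineSeries":
        return CineSeries(data=data, spacing=self.spacing)


@dataclass
class SegmentationSet:
    """Per-phase label volumes on the same grid as a :class:`CineSeries`."""

    labels: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 4:
            raise ValueError("segmentation must be 4D (x, y, slice, phase)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.uint8)
        present = np.unique(self.labels)
        if not set(present.tolist()) <= {LABEL_BACKGROUND, LABEL_CAVITY, LABEL_MYOCARDIUM}:
            raise ValueError(f"label codes must be a subset of {{0, 1, 2}}, found {present}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def n_phases(self) -> int:
        return self.labels.shape[3]

    @property
    def voxel_volume_ul(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def phase(self, p: int) -> np.ndarray:
        return self.labels[:, :, :, p]

    def mask(self, label: int, p: int | None = None) -> np.ndarray:
        """Boolean mask of ``label``, for one phase or the full 4D set."""
        if p is None:
            return self.labels == label
        return self.labels[:, :, :, p] == label

    def copy(self) -> "SegmentationSet":
        return replace(self, labels=self.labels.copy())


def check_same_grid(series: CineSeries, seg: SegmentationSet) -> None:
    """Raise if a series and a segmentation do not share grid and spacing."""
    if series.data.shape != seg.labels.shape:
        raise ValueError(
            f"series shape {series.data.shape} does not match segmentation shape {seg.labels.shape}"
        )
    if not np.allclose(series.spacing, seg.spacing):
        raise ValueError(f"spacing mismatch: {series.spacing} vs {seg.spacing}")
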