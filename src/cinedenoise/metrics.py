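"""SNR and CNR on a mid-ventricular short-axis slice at end-diastole.

SNR of a tissue is the mean intensity in its ROI divided by the raw
(uncorrected) SD of the background ROI; CNR is the difference between the
blood and myocardium SNRs.  Because signal-free magnitude background is
Rayleigh rather than Gaussian, the raw background SD is ``sigma *
sqrt(2 - pi/2)`` — the Rayleigh-corrected channel sigma lives in
:mod:`cinedenoise.noise` and is used only by the denoisers, never here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LABEL_CAVITY, LABEL_MYOCARDIUM, CineSeries, SegmentationSet
from .noise import default_background_roi

#: minimal SNR at which the Rician distribution is treated as Gaussian
GAUSSIAN_APPROX_SNR = 4.0


@dataclass(frozen=True)
class RoiSet:
    """Blood, myocardium and background masks on one 2D slice of one phase."""

    blood_mask: np.ndarray
    myo_mask: np.ndarray
    background_mask: np.ndarray
    slice_index: int
    phase_index: int

    def __post_init__(self) -> None:
        masks = (self.blood_mask, self.myo_mask, self.background_mask)
        names = ("blood", "myocardium", "background")
        shape = masks[0].shape
        for name, m in zip(names, masks):
            if m.dtype != bool or m.ndim != 2:
                raise ValueError(f"{name} mask must be a 2D boolean array")
            if m.shape != shape:
                raise ValueError("ROI masks must share one shape")
            if not m.any():
                raise ValueError(f"{name} ROI is empty")
        if (self.blood_mask & self.myo_mask).any() or (self.blood_mask & self.background_mask).any() \
                or (self.myo_mask & self.background_mask).any():
            raise ValueError("ROI masks must be pairwise disjoint")


@dataclass(frozen=True)
class QualityMetrics:
    snr_blood: float
    snr_myo: float
    cnr: float
    gaussian_approx_valid: bool

    def __post_init__(self) -> None:
        if abs(self.cnr - (self.snr_blood - self.snr_myo)) > 1e-12:
            raise ValueError("cnr must equal snr_blood - snr_myo")


def compute_snr(slice_image: np.ndarray, roi_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Mean ROI intensity over the raw background SD (denominator n - 1)."""
    img = np.asarray(slice_image, dtype=np.float64)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not roi_mask.any() or not background_mask.any():
        raise ValueError("ROI and background masks must be non-empty")
    if (roi_mask & background_mask).any():
        raise ValueError("ROI and background masks must be disjoint")
    bg = img[background_mask]
    if bg.size < 2:
        raise ValueError("background mask must select at least 2 voxels")
    sd = float(bg.std(ddof=1))
    if sd == 0:
        raise ValueError("background SD is zero (uniform background); SNR undefined")
    return float(img[roi_mask].mean()) / sd


def compute_cnr(snr_blood: float, snr_myo: float) -> float:
    """Contrast-to-noise ratio: the difference of the two tissue SNRs."""
    if not (np.isfinite(snr_blood) and np.isfinite(snr_myo)):
        raise ValueError("SNRs must be finite")
    return snr_blood - snr_myo


def quality_report(series: CineSeries, rois: RoiSet) -> QualityMetrics:
    """Both SNRs and the CNR on the ROI slice/phase of ``series``.

    ``gaussian_approx_valid`` records whether the smaller SNR exceeds 4, the
    level above which Rician noise is well approximated by a Gaussian.
    """
    if not (0 <= rois.slice_index < series.data.shape[2]):
        raise ValueError("ROI slice index out of range for series")
    if not (0 <= rois.phase_index < series.n_phases):
        raise ValueError("ROI phase index out of range for series")
    img = series.data[:, :, rois.slice_index, rois.phase_index]
    snr_blood = compute_snr(img, rois.blood_mask, rois.background_mask)
    snr_myo = compute_snr(img, rois.myo_mask, rois.background_mask)
    return QualityMetrics(
        snr_blood=snr_blood,
        snr_myo=snr_myo,
        cnr=compute_cnr(snr_blood, snr_myo),
        gaussian_approx_valid=bool(min(snr_blood, snr_myo) > GAUSSIAN_APPROX_SNR),
    )


def default_rois(truth_seg: SegmentationSet, background_size: int = 24) -> RoiSet:
    """ROIs built once from ground-truth masks and reused across conditions.

    End-diastole is the phase of maximal cavity volume and the slice is the
    middle ventricle-containing one.  The blood ROI is the eroded cavity, the
    myocardium ROI the eroded wall, and the background ROI the bottom-right
    in-plane corner.
    """
    cavity_counts = (truth_seg.labels == LABEL_CAVITY).sum(axis=(0, 1, 2))
    if cavity_counts.max() == 0:
        raise ValueError("segmentation has no cavity")
    phase = int(np.argmax(cavity_counts))
    slices_with_cavity = np.nonzero((truth_seg.labels[:, :, :, phase] == LABEL_CAVITY).any(axis=(0, 1)))[0]
    slice_index = int(slices_with_cavity[len(slices_with_cavity) // 2])
    plane = truth_seg.labels[:, :, slice_index, phase]

    blood = plane == LABEL_CAVITY
    for it in (3, 2, 1, 0):
        eroded = ndimage.binary_erosion(blood, iterations=it) if it else blood
        if eroded.any():
            blood_roi = eroded
            break
    myo = plane == LABEL_MYOCARDIUM
    eroded_myo = ndimage.binary_erosion(myo)
    myo_roi = eroded_myo if eroded_myo.any() else myo
    background = default_background_roi(plane, size=background_size)
    return RoiSet(
        blood_mask=blood_roi,
        myo_mask=myo_roi,
        background_mask=background,
        slice_index=slice_index,
        phase_index=phase,
    )
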