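"""Cardiac-function parameters from a per-phase segmentation.

EDV and ESV are the cavity volumes at the phases of maximal and minimal
filling, EF = 100 * (EDV - ESV) / EDV, and left-ventricular mass is the
segmented myocardial volume times the tissue density 1.05 g/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LABEL_CAVITY, LABEL_MYOCARDIUM, MYOCARDIAL_DENSITY_G_PER_CM3, SegmentationSet

#: mg per mm^3, numerically equal to g per cm^3
_DENSITY_MG_PER_MM3 = MYOCARDIAL_DENSITY_G_PER_CM3

LVM_PHASE_POLICIES = ("ed", "es", "mean")


@dataclass(frozen=True)
class CardiacFunction:
    """EDV/ESV in microlitres, EF in percent, LVM in milligrams."""

    edv: float
    esv: float
    ef: float
    lvm: float
    ed_phase: int
    es_phase: int

    def __post_init__(self) -> None:
        if not (self.edv >= self.esv > 0):
            raise ValueError(f"need EDV >= ESV > 0, got EDV={self.edv}, ESV={self.esv}")
        if not (0.0 <= self.ef < 100.0):
            raise ValueError(f"EF must be in [0, 100), got {self.ef}")
        if abs(self.ef - 100.0 * (self.edv - self.esv) / self.edv) > 1e-9:
            raise ValueError("EF inconsistent with EDV and ESV")
        if self.lvm <= 0:
            raise ValueError("LVM must be positive")


def phase_volumes(seg: SegmentationSet, label: int) -> np.ndarray:
    """Per-phase volume of ``label`` in microlitres (voxel count x voxel volume).

    A phase where the label is absent contributes 0; it is an error only if the
    label appears in no phase at all.
    """
    if label not in (LABEL_CAVITY, LABEL_MYOCARDIUM):
        raise ValueError(f"label must be 1 (cavity) or 2 (myocardium), got {label}")
    counts = (seg.labels == label).sum(axis=(0, 1, 2))
    if counts.sum() == 0:
        raise ValueError(f"label {label} absent from every phase")
    return counts.astype(np.float64) * seg.voxel_volume_ul


def compute_function(seg: SegmentationSet, lvm_phase_policy: str = "ed") -> CardiacFunction:
    """Derive EDV, ESV, EF and LVM from a segmentation.

    End-diastole/end-systole are the phases of maximal/minimal cavity volume.
    ``lvm_phase_policy`` selects the phase whose myocardial volume defines the
    mass: ``"ed"`` (default), ``"es"``, or ``"mean"`` over all phases.
    """
    if lvm_phase_policy not in LVM_PHASE_POLICIES:
        raise ValueError(f"lvm_phase_policy must be one of {LVM_PHASE_POLICIES}")
    cavity = phase_volumes(seg, LABEL_CAVITY)
    if int((cavity > 0).sum()) < 2:
        raise ValueError("need at least 2 phases with a non-empty cavity")
    ed_phase = int(np.argmax(cavity))
    es_phase = int(np.argmin(cavity))
    edv = float(cavity[ed_phase])
    esv = float(cavity[es_phase])
    if edv <= 0:
        raise ValueError("end-diastolic volume is zero; segmentation has no cavity")
    ef = 100.0 * (edv - esv) / edv
    myo = phase_volumes(seg, LABEL_MYOCARDIUM)
    if lvm_phase_policy == "ed":
        myo_mm3 = float(myo[ed_phase])
    elif lvm_phase_policy == "es":
        myo_mm3 = float(myo[es_phase])
    else:
        myo_mm3 = float(myo.mean())
    lvm_mg = myo_mm3 * _DENSITY_MG_PER_MM3
    return CardiacFunction(edv=edv, esv=esv, ef=ef, lvm=lvm_mg, ed_phase=ed_phase, es_phase=es_phase)
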