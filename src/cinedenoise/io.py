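"""NIfTI-1 I/O for cine series and label maps, plus flat ground-truth files."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import CineSeries, SegmentationSet
from .phantom import PhantomTruth


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_series(series: CineSeries, path: str | Path) -> None:
    """Write a cine series as 4D float32 NIfTI-1 with spacing in the header."""
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series.spacing))
    img.header.set_zooms((*series.spacing, 1.0))
    nib.save(img, str(path))


def read_series(path: str | Path, expect_phases: int | None = None) -> CineSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D cine file, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    series = CineSeries(data=data, spacing=spacing)
    if expect_phases is not None and series.n_phases != expect_phases:
        raise ValueError(f"{path}: has {series.n_phases} phases, expected {expect_phases}")
    return series


def write_seg(seg: SegmentationSet, path: str | Path) -> None:
    """Write a label map as 4D uint8 NIfTI-1."""
    img = nib.Nifti1Image(seg.labels.astype(np.uint8), _affine(seg.spacing))
    img.header.set_zooms((*seg.spacing, 1.0))
    nib.save(img, str(path))


def read_seg(path: str | Path) -> SegmentationSet:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.uint8)
    if labels.ndim != 4:
        raise ValueError(f"{path}: expected a 4D label file, got {labels.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SegmentationSet(labels=labels, spacing=spacing)


def write_truth_scalars(truth: PhantomTruth, path: str | Path) -> None:
    """Ground-truth scalars as a flat ``key: value`` text file."""
    fn = truth.true_function
    lines = {
        "sigma": truth.sigma,
        "edv_ul": fn.edv,
        "esv_ul": fn.esv,
        "ef_pct": fn.ef,
        "lvm_mg": fn.lvm,
        "ed_phase": fn.ed_phase,
        "es_phase": fn.es_phase,
    }
    lines.update({f"config.{k}": v for k, v in asdict(truth.config).items()})
    with open(path, "w") as fh:
        for key, value in lines.items():
            fh.write(f"{key}: {value}\n")


def read_truth_scalars(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if ":" not in line:
                continue
            key, value = line.split(":", 1)
            try:
                out[key.strip()] = float(value)
            except ValueError:
                pass
    return out
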