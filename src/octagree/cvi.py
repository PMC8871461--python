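"""Choroidal vascularity index: binarise the choroid into luminal (dark,
vascular) and stromal (bright) areas and report luminal/total.

The choroidal ROI spans the full choroid thickness (anterior boundary to the
choroid–scleral interface) within the central 3 mm.  Binarisation is a
Niblack-style local threshold ``T = m − k·s`` where the window mean ``m`` and
standard deviation ``s`` are computed from ROI pixels only; pixels below the
threshold are luminal (vessel lumens are hyporeflective).  Because the
threshold is relative to local statistics, the CVI is invariant under any
monotone affine rescaling of the ROI intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from ._local import masked_local_stats
from .core import BScanImage, LayerModel, ROIMask, as_float


@dataclass(frozen=True)
class CVIParams:
    window: int = 51
    k: float = 0.05


@dataclass
class BinarizationResult:
    luminal_mask: np.ndarray
    mean_threshold: float
    flags: tuple[str, ...] = ()


@dataclass
class CVIResult:
    total_area_px: int
    luminal_area_px: int
    cvi: float
    threshold_map_summary: float
    flags: tuple[str, ...] = ()

    @property
    def cvi_exact(self) -> Fraction:
        return Fraction(self.luminal_area_px, self.total_area_px)


def choroid_roi(layers: LayerModel, lateral_roi: ROIMask) -> ROIMask:
    """Choroidal ROI: choroid-anterior ≤ depth < choroid–scleral interface,
    columns inside the lateral ROI; outlined in the EDI frame."""
    ant = layers["choroid_anterior"]
    scl = layers["choroid_scleral"]
    h, w = lateral_roi.mask.shape
    if layers.width != w:
        raise ValueError("layer model width does not match the ROI")
    cols = lateral_roi.mask.any(axis=0)
    if np.any(scl[cols] < ant[cols]):
        raise ValueError("invalid segmentation: choroid curves cross")
    rows = np.arange(h, dtype=float)[:, None]
    band = (rows >= ant[None, :]) & (rows < scl[None, :]) & lateral_roi.mask
    if not band.any():
        raise ValueError("zero-thickness choroid: empty ROI")
    return ROIMask(band, kind="choroid-CVI", origin_mode=lateral_roi.origin_mode,
                   transferred=lateral_roi.transferred)


def binarize_choroid(
    image: BScanImage,
    roi: ROIMask,
    params: CVIParams = CVIParams(),
) -> BinarizationResult:
    """Niblack-style local binarisation of the choroidal ROI.

    A window larger than the ROI bounding box is rejected; a uniform ROI
    gives a degenerate threshold and is flagged rather than rejected.
    """
    if not roi.mask.any():
        raise ValueError("empty choroidal ROI")
    rows = np.any(roi.mask, axis=1)
    cols = np.any(roi.mask, axis=0)
    bbox_h = int(rows.sum())
    bbox_w = int(cols.sum())
    if params.window > max(bbox_h, bbox_w):
        raise ValueError(
            f"threshold window {params.window} exceeds ROI bounding box "
            f"({bbox_h}×{bbox_w})"
        )
    px = as_float(image)
    mean, std = masked_local_stats(px, roi.mask, params.window)
    threshold = mean - params.k * std
    luminal = (px < threshold) & roi.mask
    flags: tuple[str, ...] = ()
    roi_vals = px[roi.mask]
    if roi_vals.std() == 0:
        flags = ("degenerate-threshold: uniform ROI intensities",)
    return BinarizationResult(
        luminal_mask=luminal,
        mean_threshold=float(np.nanmean(np.where(roi.mask, threshold, np.nan))),
        flags=flags,
    )


def compute_cvi(
    luminal: BinarizationResult | np.ndarray,
    roi: ROIMask,
) -> CVIResult:
    """CVI = luminal area / total choroidal ROI area (exact rational,
    reported as float with full precision)."""
    if isinstance(luminal, BinarizationResult):
        mask = luminal.luminal_mask
        mean_thr = luminal.mean_threshold
        flags = luminal.flags
    else:
        mask = np.asarray(luminal, dtype=bool)
        mean_thr = float("nan")
        flags = ()
    total = int(roi.mask.sum())
    if total == 0:
        raise ValueError("empty choroidal ROI")
    if np.any(mask & ~roi.mask):
        raise ValueError("luminal mask extends outside the ROI")
    lum = int(mask.sum())
    return CVIResult(
        total_area_px=total,
        luminal_area_px=lum,
        cvi=lum / total,
        threshold_map_summary=mean_thr,
        flags=flags,
    )
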