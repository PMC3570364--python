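"""Trachea-recalibrated lung densitometry: Perc15, %LAA-950, lung volume.

Scanner calibration drift is removed by shifting the whole volume so the
mean air density measured inside the trachea equals -1000 HU.  Emphysema is
then scored on the lung parenchyma with the airway lumen excluded:

* ``Perc15`` — the HU value below which 15% of lung voxels fall (closer to
  -1000 means more emphysema);
* ``%LAA-950`` — the percentage of lung voxels below -950 HU, reported with
  its natural-log transform (the raw percentage is right-skewed).

Percentiles use linear interpolation between order statistics (the common
"type 7" convention).  %LAA values below 0.1% are floored to 0.1% before the
log so subjects without any low-attenuation voxels remain finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import RunConfig
from .volume import CTVolume, LabelVolume


@dataclass
class DensitometryResult:
    perc15_hu: float
    laa950_pct: float
    log_laa950: float
    lung_volume_l: float
    calibration_shift_hu: float


def recalibrate_hu(
    ct: CTVolume, trachea_mask: np.ndarray, erode_voxels: int = 2
) -> tuple[CTVolume, float]:
    """Shift the whole scan so trachea air averages -1000 HU.

    The trachea mask is eroded (default 2 voxels) before averaging so
    partial-volume voxels at the wall do not bias the air estimate; erosion
    is skipped if it would empty the mask.
    """
    mask = np.asarray(trachea_mask, dtype=bool)
    if not mask.any():
        raise ValueError("trachea mask is empty")
    if erode_voxels > 0:
        eroded = ndimage.binary_erosion(mask, iterations=erode_voxels)
        if eroded.any():
            mask = eroded
    shift = -1000.0 - float(np.mean(ct.voxels[mask]))
    return (
        CTVolume(ct.voxels + shift, ct.spacing_mm, ct.origin_mm),
        shift,
    )


def compute_perc15(
    ct: CTVolume, lung_mask_excluding_airways: np.ndarray, percentile: float = 15.0
) -> float:
    """HU threshold below which ``percentile`` percent of lung voxels fall."""
    mask = np.asarray(lung_mask_excluding_airways, dtype=bool)
    n = int(mask.sum())
    if n < 100:
        raise ValueError(f"lung mask too small for densitometry ({n} voxels)")
    return float(np.percentile(ct.voxels[mask], percentile))


def compute_laa950(
    ct: CTVolume,
    lung_mask_excluding_airways: np.ndarray,
    threshold_hu: float = -950.0,
    log_floor_pct: float = 0.1,
) -> tuple[float, float]:
    """Percentage of lung voxels below the threshold, and its natural log."""
    mask = np.asarray(lung_mask_excluding_airways, dtype=bool)
    n = int(mask.sum())
    if n < 100:
        raise ValueError(f"lung mask too small for densitometry ({n} voxels)")
    pct = float(100.0 * np.mean(ct.voxels[mask] < threshold_hu))
    return pct, math.log(max(pct, log_floor_pct))


def compute_lung_volume(lung_mask: np.ndarray, spacing_mm) -> float:
    """Voxel count times voxel volume, in liters."""
    dx, dy, dz = spacing_mm
    if min(dx, dy, dz) <= 0:
        raise ValueError("spacings must be positive")
    return float(np.count_nonzero(lung_mask) * dx * dy * dz / 1e6)


def airway_excluded_lung_mask(labels: LabelVolume) -> np.ndarray:
    """Lung (lobe) voxels minus the airway lumen dilated by one voxel.

    Dilation removes the partial-volume rim around the lumen; the exclusion
    is applied before the percentile denominator is formed.
    """
    lung = labels.lung_mask()
    airway = ndimage.binary_dilation(labels.lumen_mask(include_trachea=True))
    return lung & ~airway


def densitometry(
    ct: CTVolume,
    labels: LabelVolume,
    config: RunConfig | None = None,
    recalibrate: bool = True,
) -> DensitometryResult:
    """Full densitometry of one subject from CT plus labels."""
    config = config or RunConfig()
    shift = 0.0
    if recalibrate:
        ct, shift = recalibrate_hu(ct, labels.trachea_mask())
    mask = airway_excluded_lung_mask(labels)
    perc15 = compute_perc15(ct, mask, config.perc_percentile)
    laa, log_laa = compute_laa950(
        ct, mask, config.laa_threshold_hu, config.laa_log_floor_pct
    )
    volume_l = compute_lung_volume(labels.lung_mask(), labels.spacing_mm)
    return DensitometryResult(
        perc15_hu=perc15,
        laa950_pct=laa,
        log_laa950=log_laa,
        lung_volume_l=volume_l,
        calibration_shift_hu=shift,
    )
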