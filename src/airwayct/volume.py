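"""In-memory CT and label volumes plus NIfTI/MetaImage round-trip I/O.

Conventions used throughout the package:

* voxel arrays are indexed ``[x, y, z]`` with ``z`` the slice direction;
* all world coordinates and spacings are millimetres;
* HU values are clipped to the CT scanner range [-1024, 3071].
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

HU_MIN = -1024.0
HU_MAX = 3071.0

#: canonical label legend shared by the phantom generator and all readers
DEFAULT_LEGEND: dict[int, str] = {
    0: "outside",
    1: "LUL",
    2: "LLL",
    3: "RUL",
    4: "RML",
    5: "RLL",
    6: "trachea",
    7: "airway_lumen",
}

LOBE_NAMES = ("LUL", "LLL", "RUL", "RML", "RLL")
LOBE_CODES = tuple(c for c, n in DEFAULT_LEGEND.items() if n in LOBE_NAMES)
TRACHEA_CODE = 6
LUMEN_CODE = 7

_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class CTVolume:
    """A 3D grid of HU values with anisotropic voxel spacing."""

    voxels: np.ndarray  # (nx, ny, nz), float
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume requires a 3D voxel array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacings must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for world coordinates (mm)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (p - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx * np.asarray(self.spacing_mm) + np.asarray(self.origin_mm)

    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz


@dataclass
class LabelVolume:
    """Categorical companion of a :class:`CTVolume` (lobes, trachea, lumen)."""

    labels: np.ndarray  # (nx, ny, nz), integer codes
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume requires a 3D label array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def _codes(self, names) -> list[int]:
        wanted = set(names)
        return [c for c, n in self.legend.items() if n in wanted]

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of voxels whose label name is in ``names``."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for c in self._codes(names):
            out |= self.labels == c
        return out

    def lung_mask(self) -> np.ndarray:
        return self.mask(*LOBE_NAMES)

    def trachea_mask(self) -> np.ndarray:
        return self.mask("trachea")

    def lumen_mask(self, include_trachea: bool = True) -> np.ndarray:
        names = ("airway_lumen", "trachea") if include_trachea else ("airway_lumen",)
        return self.mask(*names)


def _check_extension(path: str) -> None:
    if not any(str(path).endswith(e) for e in _EXTENSIONS):
        raise ValueError(
            f"unrecognized volume extension for {path!r}; expected one of {_EXTENSIONS}"
        )


def _to_sitk(voxels: np.ndarray, spacing, origin) -> sitk.Image:
    # SimpleITK expects (z, y, x) arrays; our arrays are (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def write_volume(vol: CTVolume | LabelVolume, path: str) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    _check_extension(path)
    if isinstance(vol, LabelVolume):
        img = _to_sitk(vol.labels.astype(np.uint8), vol.spacing_mm, vol.origin_mm)
    else:
        img = _to_sitk(vol.voxels.astype(np.float64), vol.spacing_mm, vol.origin_mm)
    sitk.WriteImage(img, str(path))


def read_volume(path: str) -> CTVolume:
    _check_extension(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return CTVolume(arr.astype(np.float64), spacing, origin)


def read_labels(path: str, legend: dict[int, str] | None = None) -> LabelVolume:
    _check_extension(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return LabelVolume(
        arr.astype(np.int16), spacing, origin, legend or dict(DEFAULT_LEGEND)
    )
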