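"""Digital CT phantoms of airway trees embedded in lung parenchyma.

The generator produces CT-like volumes at the acquisition geometry of a
low-dose screening protocol (512x512-equivalent in-plane matrix, 1 mm slices
reconstructed at 0.7 mm increments, soft-kernel blur), together with a label
volume (five lobes, trachea, airway lumen) and a per-branch ground-truth
table.  It is the test bed for the wall-thickness and densitometry modules:
every branch carries its true lumen diameter and wall thickness, and the
parenchyma carries a controllable low-attenuation (emphysema) fraction.

Model choices
-------------
* The soft reconstruction kernel is modelled as an isotropic in-plane
  Gaussian PSF (FWHM ``psf_fwhm_mm``) plus slice-direction averaging over
  ``slice_thickness_mm``; only the blur scale matters to the integral-based
  wall measurement, which is designed to be robust to it.
* Tissue densities (HU): lumen and trachea air -1000, airway wall 0 (soft
  tissue), parenchyma -880, emphysema -980, outside-lung background +20.
* Emphysema is placed as spherical low-attenuation blobs (radius 2-6 mm),
  giving spatially coherent low-attenuation areas like centrilobular
  disease; blob placement is sequential so a larger target fraction extends
  (never rearranges) the blob set of a smaller one under the same seed.
* An ``adjacent_vessel`` on a branch is modelled as a same-density collar
  subtending an exact angular fraction of the outer perimeter, so the
  perimeter fraction occluded to the outer-border search is known exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import (
    CTVolume,
    DEFAULT_LEGEND,
    HU_MAX,
    HU_MIN,
    LabelVolume,
    LOBE_NAMES,
    LUMEN_CODE,
    TRACHEA_CODE,
)

AIR_HU = -1000.0
WALL_HU = 0.0
PARENCHYMA_HU = -880.0
EMPHYSEMA_HU = -980.0
OUTSIDE_HU = 20.0

_NAME_TO_CODE = {v: k for k, v in DEFAULT_LEGEND.items()}


# ---------------------------------------------------------------------------
# acquisition geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scan geometry and degradation parameters of one acquisition."""

    fov_mm: float = 350.0
    matrix: int = 512
    slice_thickness_mm: float = 1.0
    slice_increment_mm: float = 0.7
    psf_fwhm_mm: float = 0.7
    noise_sd_hu: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")
        if self.matrix < 64:
            raise ValueError("matrix must be >= 64")
        if self.slice_increment_mm > self.slice_thickness_mm:
            raise ValueError("slice_increment_mm must be <= slice_thickness_mm")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")

    @property
    def pixel_spacing_mm(self) -> float:
        return pixel_spacing_from_fov(self.fov_mm, self.matrix)


def pixel_spacing_from_fov(fov_mm: float, matrix: int) -> float:
    """In-plane pixel spacing of a reconstruction: FOV divided by matrix."""
    if fov_mm <= 0 or matrix < 1:
        raise ValueError("fov_mm and matrix must be positive")
    return fov_mm / matrix


# ---------------------------------------------------------------------------
# branch geometry and scene truth
# ---------------------------------------------------------------------------


@dataclass
class BranchSpec:
    """Ground truth for one airway branch (a straight capsule segment)."""

    branch_id: int
    parent_id: int | None
    lobe: str | None  # one of LOBE_NAMES, or None for trachea/main stem
    generation: int  # topological order, trachea root = 0
    centerline: np.ndarray  # (n, 3) world mm, ordered root -> periphery
    lumen_diameter_mm: float
    wall_thickness_mm: float
    wall_hu: float = WALL_HU
    adjacent_vessel: bool = False
    vessel_fraction: float = 0.25  # perimeter fraction covered by the vessel
    vessel_azimuth_deg: float = 0.0

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.lumen_diameter_mm <= 0 or self.wall_thickness_mm <= 0:
            raise ValueError("lumen diameter and wall thickness must be positive")

    @property
    def lumen_radius_mm(self) -> float:
        return self.lumen_diameter_mm / 2.0

    @property
    def outer_radius_mm(self) -> float:
        return self.lumen_radius_mm + self.wall_thickness_mm

    @property
    def length_mm(self) -> float:
        return float(
            np.sum(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1))
        )


@dataclass
class PhantomTruth:
    """Scene-level ground truth; densitometry fields are filled at raster time."""

    branches: list[BranchSpec]
    parenchyma_hu: float = PARENCHYMA_HU
    emphysema_fraction: float = 0.0
    emphysema_hu: float = EMPHYSEMA_HU
    trachea_offset_hu: float = 0.0
    truth_perc15_hu: float | None = None
    truth_laa950_pct: float | None = None
    achieved_emphysema_fraction: float | None = None
    lung_volume_ml: float | None = None  # analytic elliptic-cylinder volume
    lung_geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.emphysema_fraction <= 1:
            raise ValueError("emphysema_fraction must be in [0, 1]")
        if self.emphysema_fraction > 0 and self.emphysema_hu >= -950:
            raise ValueError("emphysema_hu must be < -950 when emphysema is present")

    def branch_by_id(self) -> dict[int, BranchSpec]:
        return {b.branch_id: b for b in self.branches}


DEFAULT_DIAMETERS: dict[int, float] = {
    0: 12.0,
    1: 9.0,
    2: 7.0,
    3: 5.6,
    4: 4.5,
    5: 3.5,
    6: 2.8,
    7: 2.2,
}

# Representative path length per generation (mm).  A monopodial
# one-path-per-lobe tree cannot carry the 2**g branches of a real dichotomous
# tree, so the representative length carries the abundance of measurable
# airways per generation instead: it rises toward the generation whose
# caliber crosses 3.5 mm (where real trees concentrate the most assessable
# wall perimeter) and falls again as airways become subresolution.
DEFAULT_LENGTHS: dict[int, float] = {
    0: 25.0,
    1: 16.0,
    2: 14.0,
    3: 13.0,
    4: 16.0,
    5: 22.0,
    6: 14.0,
    7: 7.0,
}

# azimuth (deg, from +x) and initial tilt from vertical (deg) per lobe
_LOBE_LAYOUT = {
    "LUL": (150.0, 55.0),
    "LLL": (210.0, 45.0),
    "RUL": (30.0, 55.0),
    "RML": (330.0, 50.0),
    "RLL": (300.0, 42.0),
}
_TILT_STEP_DEG = 8.0  # branches steepen toward vertical with depth
_MIN_TILT_DEG = 15.0
_STUB_LENGTH_MM = 9.0


def _direction(azimuth_deg: float, tilt_deg: float) -> np.ndarray:
    az = math.radians(azimuth_deg)
    tl = math.radians(tilt_deg)
    return np.array(
        [math.sin(tl) * math.cos(az), math.sin(tl) * math.sin(az), -math.cos(tl)]
    )


def _segment(p0: np.ndarray, direction: np.ndarray, length: float) -> np.ndarray:
    n = max(2, int(math.ceil(length)) + 1)
    t = np.linspace(0.0, length, n)[:, None]
    return p0[None, :] + t * direction[None, :]


def build_airway_tree(
    template: str = "five-lobe",
    per_generation_diameters: dict[int, float] | None = None,
    wall_fraction: float = 0.18,
    seed: int = 0,
    per_generation_lengths: dict[int, float] | None = None,
) -> list[BranchSpec]:
    """Build a rooted bifurcating airway tree as straight capsule branches.

    Templates:

    * ``"single"`` — one straight branch (generation 1), for degenerate tests;
    * ``"five-lobe"`` — trachea, main bronchi, bronchus intermedius and a
      monopodial path per lobe down to the deepest generation in the diameter
      map, with a short stub sibling at every path junction so each internal
      node bifurcates.
    """
    diam = dict(per_generation_diameters or DEFAULT_DIAMETERS)
    lengths = dict(per_generation_lengths or DEFAULT_LENGTHS)
    if not 0 < wall_fraction < 1:
        raise ValueError("wall_fraction must be in (0, 1)")
    gens = sorted(diam)
    vals = [diam[g] for g in gens]
    if any(b >= a for a, b in zip(vals, vals[1:])):
        raise ValueError("per-generation diameters must be strictly decreasing")

    def wt(g: int) -> float:
        return wall_fraction * diam[g]

    if template == "single":
        # one measurable branch at the caliber of interest: use the map
        # diameter closest to 3.5 mm
        g = min(gens, key=lambda k: abs(diam[k] - 3.5))
        cl = _segment(np.array([0.0, 0.0, 20.0]), np.array([0.0, 0.0, -1.0]), 40.0)
        return [BranchSpec(0, None, "RUL", 1, cl, diam[g], wt(g))]

    if template != "five-lobe":
        raise ValueError(f"unknown template {template!r}")

    rng = np.random.default_rng(seed)
    max_gen = gens[-1]
    branches: list[BranchSpec] = []
    next_id = [0]

    def add(parent, lobe, gen, p0, direction, length, **kw) -> BranchSpec:
        b = BranchSpec(
            next_id[0],
            None if parent is None else parent.branch_id,
            lobe,
            gen,
            _segment(p0, direction, length),
            diam[gen],
            wt(gen),
            **kw,
        )
        next_id[0] += 1
        branches.append(b)
        return b

    carina = np.array([0.0, 0.0, 0.0])
    trachea = add(
        None, None, 0, carina + np.array([0.0, 0.0, lengths[0]]),
        np.array([0.0, 0.0, -1.0]), lengths[0],
    )
    left_main = add(trachea, None, 1, carina, _direction(180.0, 55.0), lengths[1])
    right_main = add(trachea, None, 1, carina, _direction(345.0, 55.0), lengths[1])
    intermedius = add(
        right_main, "RLL", 2, right_main.centerline[-1],
        _direction(315.0, 40.0), lengths[2],
    )

    lobe_entry = {
        "LUL": (left_main, 2),
        "LLL": (left_main, 2),
        "RUL": (right_main, 2),
        "RML": (intermedius, 3),
        "RLL": (intermedius, 3),
    }

    for lobe in LOBE_NAMES:
        parent, entry_gen = lobe_entry[lobe]
        azimuth, tilt = _LOBE_LAYOUT[lobe]
        p0 = parent.centerline[-1]
        prev = parent
        for k, g in enumerate(range(entry_gen, max_gen + 1)):
            zig = 12.0 * (1 if k % 2 == 0 else -1) + rng.uniform(-3.0, 3.0)
            az = azimuth + zig
            tl = max(_MIN_TILT_DEG, tilt - _TILT_STEP_DEG * k)
            d = _direction(az, tl)
            br = add(prev, lobe, g, p0, d, lengths[g])
            if g < max_gen:  # stub sibling of the next path branch
                stub_dir = _direction(az + 55.0, min(80.0, tl + 20.0))
                add(br, lobe, g + 1, br.centerline[-1], stub_dir, _STUB_LENGTH_MM)
            prev = br
            p0 = br.centerline[-1]

    return branches


def branch_children(branches: list[BranchSpec]) -> dict[int, list[int]]:
    out: dict[int, list[int]] = {b.branch_id: [] for b in branches}
    for b in branches:
        if b.parent_id is not None:
            out[b.parent_id].append(b.branch_id)
    return out


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _capsule_fields(shape, spacing, origin, branch: BranchSpec):
    """Yield (index-slices, distance-to-axis, axial/radial info) for a branch.

    Works segment by segment on the branch polyline; each segment is treated
    as a capsule (cylinder with spherical caps), so consecutive segments and
    parent/child joints fuse seamlessly.
    """
    spacing = np.asarray(spacing)
    origin = np.asarray(origin)
    pts = branch.centerline
    reach = branch.outer_radius_mm + (3.5 if branch.adjacent_vessel else 0.0) + 1.0
    for p0, p1 in zip(pts[:-1], pts[1:]):
        lo = np.minimum(p0, p1) - reach
        hi = np.maximum(p0, p1) + reach
        i0 = np.maximum(0, np.floor((lo - origin) / spacing)).astype(int)
        i1 = np.minimum(shape, np.ceil((hi - origin) / spacing).astype(int) + 1)
        if np.any(i0 >= i1):
            continue
        sl = tuple(slice(a, b) for a, b in zip(i0, i1))
        xs = origin[0] + spacing[0] * np.arange(i0[0], i1[0])
        ys = origin[1] + spacing[1] * np.arange(i0[1], i1[1])
        zs = origin[2] + spacing[2] * np.arange(i0[2], i1[2])
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        q = np.stack([gx, gy, gz], axis=-1) - p0
        axis = p1 - p0
        seg_len = np.linalg.norm(axis)
        u = axis / seg_len
        t = np.clip(q @ u, 0.0, seg_len)
        perp = q - t[..., None] * u
        dist = np.linalg.norm(perp, axis=-1)
        yield sl, dist, perp, u


def _blur(clean: np.ndarray, acq: AcquisitionSpec, spacing) -> np.ndarray:
    out = clean
    if acq.psf_fwhm_mm > 0:
        sigma_mm = acq.psf_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        out = ndimage.gaussian_filter(
            out, sigma=(sigma_mm / spacing[0], sigma_mm / spacing[1], 0.0)
        )
    # slice-direction averaging over the slice thickness
    kernel = _boxcar_kernel(acq.slice_thickness_mm, spacing[2])
    if kernel.size > 1:
        out = ndimage.convolve1d(out, kernel, axis=2, mode="nearest")
    return out


def _boxcar_kernel(width_mm: float, dz_mm: float) -> np.ndarray:
    """Discrete kernel of a boxcar of ``width_mm`` sampled at ``dz_mm``."""
    half = width_mm / 2.0
    n = int(math.ceil(half / dz_mm))
    centers = np.arange(-n, n + 1) * dz_mm
    w = np.clip(
        np.minimum(centers + dz_mm / 2, half) - np.maximum(centers - dz_mm / 2, -half),
        0.0,
        None,
    )
    w = w[w > 0]
    return w / w.sum()


def _supersample_factors(spacing, target_mm: float = 0.175, budget: int = 60_000_000):
    """Integer supersampling per axis so the rasterization grid resolves
    sub-voxel walls; the continuous scene is sampled on this fine grid, the
    PSF applied there, and the acquisition grid read out by decimation."""
    ss = np.maximum(1, np.ceil(np.asarray(spacing) / target_mm)).astype(int)
    return ss


def _scene_grid(branches, truth, acq):
    spacing = np.array(
        [acq.pixel_spacing_mm, acq.pixel_spacing_mm, acq.slice_increment_mm]
    )
    pts = np.vstack([b.centerline for b in branches])
    half_fov = acq.fov_mm / 2.0
    for b in branches:
        r = np.max(np.abs(b.centerline[:, :2])) + b.outer_radius_mm
        if r > half_fov - 1.0:
            raise ValueError(
                f"branch {b.branch_id} (lobe {b.lobe}, generation {b.generation}) "
                f"extends to {r:.1f} mm, outside the {acq.fov_mm:.0f} mm FOV"
            )
    zmin = pts[:, 2].min() - 10.0
    zmax = pts[:, 2].max() + 5.0
    nz = int(math.ceil((zmax - zmin) / spacing[2])) + 1
    shape = (acq.matrix, acq.matrix, nz)
    origin = np.array(
        [-half_fov + spacing[0] / 2.0, -half_fov + spacing[1] / 2.0, zmin]
    )
    return shape, spacing, origin


def _lung_geometry(branches, half_fov_mm: float | None = None) -> dict:
    """Analytic elliptic-cylinder lung region covering the non-trachea tree.

    The cylinder must both contain every branch point and fit inside the
    reconstruction FOV, so that the analytic volume matches the voxelized
    region up to a surface layer.
    """
    body = [b for b in branches if b.generation > 0] or branches
    pts = np.vstack([b.centerline for b in body])
    cx = 0.5 * (pts[:, 0].min() + pts[:, 0].max())
    cy = 0.5 * (pts[:, 1].min() + pts[:, 1].max())
    margin = 12.0
    a = np.max(np.abs(pts[:, 0] - cx)) + margin
    bsemi = np.max(np.abs(pts[:, 1] - cy)) + margin
    # grow the ellipse until every branch point is comfortably inside
    # (a bounding-box margin alone can miss points extreme in both axes)
    ecc = np.sqrt(
        ((pts[:, 0] - cx) / a) ** 2 + ((pts[:, 1] - cy) / bsemi) ** 2
    ).max()
    if ecc > 0.9:
        a *= ecc / 0.9
        bsemi *= ecc / 0.9
    if half_fov_mm is not None:
        a = min(a, half_fov_mm - abs(cx) - 0.5)
        bsemi = min(bsemi, half_fov_mm - abs(cy) - 0.5)
        ecc = np.sqrt(
            ((pts[:, 0] - cx) / a) ** 2 + ((pts[:, 1] - cy) / bsemi) ** 2
        ).max()
        if ecc >= 1.0:
            raise ValueError(
                "airway tree cannot be wrapped in a lung region inside the FOV"
            )
    z_top = pts[:, 2].max() + 2.0
    z_bot = pts[:, 2].min() - 8.0
    return {
        "center_xy_mm": (float(cx), float(cy)),
        "semi_axes_mm": (float(a), float(bsemi)),
        "z_range_mm": (float(z_bot), float(z_top)),
        "volume_ml": float(math.pi * a * bsemi * (z_top - z_bot) / 1000.0),
    }


def rasterize_phantom(
    branches: list[BranchSpec],
    truth: PhantomTruth,
    acq: AcquisitionSpec,
) -> tuple[CTVolume, LabelVolume]:
    """Render the scene into a CT volume and its label volume.

    The clean composition (air lumen, soft-tissue wall, parenchyma with
    emphysema blobs) is blurred with the acquisition PSF, shifted by the
    calibration drift ``truth.trachea_offset_hu``, and degraded with additive
    Gaussian noise.  Labels are computed from the unblurred geometry and are
    untouched by blur and noise.  ``truth.truth_perc15_hu`` and
    ``truth.truth_laa950_pct`` are filled from the blurred pre-noise,
    pre-drift density mix over the lung mask (airways excluded), the same
    mask rule the densitometry module applies.
    """
    blurred, labels, spacing, origin, lung_info = _compose_scene(branches, truth, acq)

    # ground-truth densitometry on the pre-noise, pre-drift volume
    lung = np.isin(labels, list(LOBE_CODES_ARR))
    airway = (labels == LUMEN_CODE) | (labels == TRACHEA_CODE)
    airway = ndimage.binary_dilation(airway)
    mask = lung & ~airway
    vals = blurred[mask]
    truth.truth_perc15_hu = float(np.percentile(vals, 15.0))
    truth.truth_laa950_pct = float(100.0 * np.mean(vals < -950.0))
    truth.lung_volume_ml = lung_info["volume_ml"]
    truth.lung_geometry = lung_info

    out = blurred + truth.trachea_offset_hu
    if acq.noise_sd_hu > 0:
        rng = np.random.default_rng(acq.seed)
        out = out + rng.normal(0.0, acq.noise_sd_hu, size=out.shape)
    np.clip(out, HU_MIN, HU_MAX, out=out)

    spacing_t = tuple(float(s) for s in spacing)
    origin_t = tuple(float(o) for o in origin)
    return (
        CTVolume(out, spacing_t, origin_t),
        LabelVolume(labels, spacing_t, origin_t),
    )


LOBE_CODES_ARR = tuple(_NAME_TO_CODE[n] for n in LOBE_NAMES)


def _lung_region_mask(shape, spacing, origin, lung_info) -> np.ndarray:
    xs = origin[0] + spacing[0] * np.arange(shape[0])
    ys = origin[1] + spacing[1] * np.arange(shape[1])
    zs = origin[2] + spacing[2] * np.arange(shape[2])
    cx, cy = lung_info["center_xy_mm"]
    a, bsemi = lung_info["semi_axes_mm"]
    z0, z1 = lung_info["z_range_mm"]
    ell = ((xs[:, None] - cx) / a) ** 2 + ((ys[None, :] - cy) / bsemi) ** 2 <= 1.0
    zin = (zs >= z0) & (zs <= z1)
    return ell[:, :, None] & zin[None, None, :]


def _compose_scene(branches, truth, acq):
    """Render the blurred, pre-noise scene (coarse grid) plus labels.

    The continuous scene is sampled on a supersampled grid (so sub-voxel
    walls keep their correct partial-volume mass), blurred with the PSF
    there, and the acquisition grid read out by decimation — mimicking how
    a scanner's continuous PSF-blurred signal is sampled by reconstruction.
    """
    shape, spacing, origin = _scene_grid(branches, truth, acq)
    lung_info = _lung_geometry(branches, acq.fov_mm / 2.0)

    ss = _supersample_factors(spacing)
    while np.prod(np.asarray(shape) * ss) > 8e7 and np.any(ss > 1):
        ss = np.maximum(1, ss // 2)
    fine_spacing = spacing / ss
    fine_shape = tuple(int(n * f) for n, f in zip(shape, ss))

    clean = _compose_clean(branches, truth, fine_shape, fine_spacing, origin, lung_info)
    blurred_fine = _blur(clean, acq, fine_spacing)
    blurred = np.ascontiguousarray(blurred_fine[:: ss[0], :: ss[1], :: ss[2]])
    del clean, blurred_fine

    labels = _compose_labels(branches, shape, spacing, origin, lung_info)
    return blurred, labels, spacing, origin, lung_info


PARENCHYMA_TEXTURE_SD_HU = 15.0
PARENCHYMA_TEXTURE_SCALE_MM = 1.5
_TEXTURE_SEED = 54321  # fixed: texture is part of the object, not the scan


def _compose_clean(branches, truth, shape, spacing, origin, lung_info) -> np.ndarray:
    clean = np.full(shape, OUTSIDE_HU, dtype=np.float64)
    lung = _lung_region_mask(shape, spacing, origin, lung_info)
    clean[lung] = truth.parenchyma_hu

    # smooth parenchymal texture: real lung tissue is not uniform, and a
    # continuous density distribution keeps percentile ground truth strictly
    # monotone in the emphysema fraction
    if PARENCHYMA_TEXTURE_SD_HU > 0:
        rng = np.random.default_rng(_TEXTURE_SEED)
        tex = rng.standard_normal(shape).astype(np.float32)
        sig = [PARENCHYMA_TEXTURE_SCALE_MM / s for s in spacing]
        tex = ndimage.gaussian_filter(tex, sig)
        sd = tex.std()
        if sd > 0:
            tex *= PARENCHYMA_TEXTURE_SD_HU / sd
        clean[lung] += tex[lung]
        del tex

    # emphysema blobs (sequential placement => nested across fractions)
    if truth.emphysema_fraction > 0:
        emph = _place_emphysema(lung, shape, spacing, origin, branches, truth, lung_info)
        clean[emph] = truth.emphysema_hu
        truth.achieved_emphysema_fraction = float(emph.sum() / lung.sum())
    else:
        truth.achieved_emphysema_fraction = 0.0
    del lung

    # airway walls, then vessels, then lumens (lumen carves through walls)
    for b in branches:
        for sl, dist, _, _ in _capsule_fields(shape, spacing, origin, b):
            clean[sl][dist <= b.outer_radius_mm] = b.wall_hu
    for b in branches:
        if not b.adjacent_vessel:
            continue
        az0 = math.radians(b.vessel_azimuth_deg)
        half_ang = b.vessel_fraction * math.pi
        for sl, dist, perp, u in _capsule_fields(shape, spacing, origin, b):
            ref = _perp_reference(u)
            ref2 = np.cross(u, ref)
            ang = np.arctan2(perp @ ref2, perp @ ref)
            dang = np.angle(np.exp(1j * (ang - az0)))
            collar = (
                (dist > b.outer_radius_mm)
                & (dist <= b.outer_radius_mm + 3.0)
                & (np.abs(dang) <= half_ang)
            )
            clean[sl][collar] = b.wall_hu
    for b in branches:
        for sl, dist, _, _ in _capsule_fields(shape, spacing, origin, b):
            clean[sl][dist <= b.lumen_radius_mm] = AIR_HU
    return clean


def _compose_labels(branches, shape, spacing, origin, lung_info) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int16)
    lung = _lung_region_mask(shape, spacing, origin, lung_info)

    # lobe partition of the lung: nearest lobe path (EDT on seed lines)
    lobe_branches = [b for b in branches if b.lobe is not None]
    if lobe_branches:
        seeds = np.zeros(shape, dtype=np.int16)
        for b in lobe_branches:
            pts = _resample_dense(b.centerline, min(spacing) / 2.0)
            idx = np.round((pts - origin) / spacing).astype(int)
            ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
            idx = idx[ok]
            seeds[idx[:, 0], idx[:, 1], idx[:, 2]] = _NAME_TO_CODE[b.lobe]
        if np.any(seeds):
            _, inds = ndimage.distance_transform_edt(
                seeds == 0, sampling=spacing, return_indices=True
            )
            nearest = seeds[inds[0], inds[1], inds[2]]
            labels[lung] = nearest[lung]

    for b in branches:
        code = TRACHEA_CODE if b.generation == 0 else LUMEN_CODE
        for sl, dist, _, _ in _capsule_fields(shape, spacing, origin, b):
            labels[sl][dist <= b.lumen_radius_mm] = code
    return labels


def _resample_dense(points: np.ndarray, step: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return points[:1]
    si = np.linspace(0.0, s[-1], max(2, int(s[-1] / step) + 1))
    return np.column_stack([np.interp(si, s, points[:, k]) for k in range(3)])


def _perp_reference(u: np.ndarray) -> np.ndarray:
    cand = np.eye(3)[np.argmin(np.abs(u))]
    v = cand - (cand @ u) * u
    return v / np.linalg.norm(v)


def _place_emphysema(lung, shape, spacing, origin, branches, truth, lung_info):
    """Place spherical blobs until the target voxel fraction is covered.

    Placement is sequential from a fixed stream, so a larger target fraction
    extends the blob set of a smaller one (nested truth across fractions).
    """
    rng = np.random.default_rng(12345)
    target = truth.emphysema_fraction * lung.sum()
    emph = np.zeros(shape, dtype=bool)
    pts = np.vstack([_resample_dense(b.centerline, 2.0) for b in branches])
    max_outer = max(b.outer_radius_mm for b in branches)
    cx, cy = lung_info["center_xy_mm"]
    a, bsemi = lung_info["semi_axes_mm"]
    z0, z1 = lung_info["z_range_mm"]
    covered = 0
    for _ in range(20000):
        if covered >= target:
            break
        center = np.array(
            [
                cx + rng.uniform(-a, a),
                cy + rng.uniform(-bsemi, bsemi),
                rng.uniform(z0, z1),
            ]
        )
        radius = rng.uniform(2.0, 6.0)
        if ((center[0] - cx) / a) ** 2 + ((center[1] - cy) / bsemi) ** 2 > 0.95:
            continue
        # keep blobs clear of the airway tree
        if np.min(np.linalg.norm(pts - center, axis=1)) < radius + max_outer + 1.0:
            continue
        lo = np.maximum(0, np.floor((center - radius - origin) / spacing)).astype(int)
        hi = np.minimum(
            shape, np.ceil((center + radius - origin) / spacing).astype(int) + 1
        )
        if np.any(lo >= hi):
            continue
        sl = tuple(slice(int(p), int(q)) for p, q in zip(lo, hi))
        xs = origin[0] + spacing[0] * np.arange(lo[0], hi[0])
        ys = origin[1] + spacing[1] * np.arange(lo[1], hi[1])
        zs = origin[2] + spacing[2] * np.arange(lo[2], hi[2])
        d2 = (
            (xs[:, None, None] - center[0]) ** 2
            + (ys[None, :, None] - center[1]) ** 2
            + (zs[None, None, :] - center[2]) ** 2
        )
        before = emph[sl].sum()
        emph[sl] |= (d2 <= radius**2) & lung[sl]
        covered += int(emph[sl].sum() - before)
    return emph


def generate_dose_pair(
    branches: list[BranchSpec],
    truth: PhantomTruth,
    acq_low: AcquisitionSpec,
    acq_high: AcquisitionSpec,
) -> tuple[CTVolume, CTVolume, LabelVolume]:
    """Two acquisitions of the same scene differing only in noise.

    ``acq_low`` is the low-dose (noisier) protocol.  Geometry fields must
    match; the noise realizations are drawn independently from each
    acquisition's seed.
    """
    geo = ("fov_mm", "matrix", "slice_thickness_mm", "slice_increment_mm",
           "psf_fwhm_mm")
    for f in geo:
        if getattr(acq_low, f) != getattr(acq_high, f):
            raise ValueError(f"dose pair geometry mismatch on {f}")
    if acq_low.noise_sd_hu < acq_high.noise_sd_hu:
        raise ValueError("low-dose acquisition must be at least as noisy as high-dose")

    blurred, labels, spacing, origin, lung_info = _compose_scene(branches, truth, acq_low)
    truth.lung_volume_ml = lung_info["volume_ml"]
    truth.lung_geometry = lung_info

    spacing_t = tuple(float(s) for s in spacing)
    origin_t = tuple(float(o) for o in origin)
    vols = []
    for acq in (acq_low, acq_high):
        out = blurred + truth.trachea_offset_hu
        if acq.noise_sd_hu > 0:
            rng = np.random.default_rng(acq.seed)
            out = out + rng.normal(0.0, acq.noise_sd_hu, size=out.shape)
        vols.append(CTVolume(np.clip(out, HU_MIN, HU_MAX), spacing_t, origin_t))
    return vols[0], vols[1], LabelVolume(labels, spacing_t, origin_t)


# ---------------------------------------------------------------------------
# convenience scenes
# ---------------------------------------------------------------------------


def single_tube_scene(
    lumen_diameter_mm: float = 3.5,
    wall_thickness_mm: float = 0.6,
    length_mm: float = 40.0,
    lobe: str = "RUL",
    adjacent_vessel: bool = False,
    vessel_fraction: float = 0.25,
) -> tuple[list[BranchSpec], PhantomTruth]:
    """A single straight axial tube in parenchyma: the unit test scene."""
    cl = _segment(
        np.array([0.0, 0.0, length_mm / 2.0]), np.array([0.0, 0.0, -1.0]), length_mm
    )
    b = BranchSpec(
        0, None, lobe, 1, cl, lumen_diameter_mm, wall_thickness_mm,
        adjacent_vessel=adjacent_vessel, vessel_fraction=vessel_fraction,
    )
    return [b], PhantomTruth(branches=[b])


def tube_acquisition(
    fov_mm: float = 60.0,
    matrix: int = 88,
    noise_sd_hu: float = 25.0,
    psf_fwhm_mm: float = 0.7,
    seed: int = 0,
) -> AcquisitionSpec:
    """Protocol voxel geometry on a small FOV around a single tube."""
    return AcquisitionSpec(
        fov_mm=fov_mm,
        matrix=matrix,
        slice_thickness_mm=1.0,
        slice_increment_mm=0.7,
        psf_fwhm_mm=psf_fwhm_mm,
        noise_sd_hu=noise_sd_hu,
        seed=seed,
    )


def truth_table(branches: list[BranchSpec]):
    """Per-branch ground truth as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    rows = [
        {
            "branch_id": b.branch_id,
            "parent_id": -1 if b.parent_id is None else b.parent_id,
            "lobe": b.lobe or "",
            "generation": b.generation,
            "lumen_diameter_mm": b.lumen_diameter_mm,
            "wall_thickness_mm": b.wall_thickness_mm,
            "length_mm": b.length_mm,
            "adjacent_vessel": b.adjacent_vessel,
        }
        for b in branches
    ]
    return pd.DataFrame(rows)
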