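"""Run-wide configuration.

The defaults below are the protocol constants of the measurement method:
wall thickness is measured at a 3.5 mm internal lumen diameter (+/- 0.25 mm),
a location counts only when at least 25% of its perimeter is assessable,
emphysema is scored as the 15th percentile of the lung density histogram
(Perc15) and the fraction of voxels below -950 HU (%LAA-950).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass
class RunConfig:
    # fixed-diameter selection
    target_diameter_mm: float = 3.5
    tol_mm: float = 0.25
    min_apf: float = 0.25
    # cross-section sampling
    n_rays: int = 32
    centerline_step_mm: float = 1.0
    ray_len_mm: float = 5.0
    ray_step_mm: float = 0.1
    skip_junction_mm: float = 2.0
    # wall measurement
    window_mm: float = 2.0
    f_out: float = 0.5
    d_max_mm: float = 2.0
    # HU reference of the (unblurred) airway wall; "auto" switches to the
    # per-section robust-peak estimate (95th percentile of ray peaks)
    hu_wall_ref: float | str = 0.0
    min_wall_contrast_hu: float = 200.0
    # densitometry
    laa_threshold_hu: float = -950.0
    perc_percentile: float = 15.0
    laa_log_floor_pct: float = 0.1
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.tol_mm < 0 or self.target_diameter_mm <= 0:
            raise ValueError("diameter/tolerance must be positive")
        if not 0 <= self.min_apf <= 1:
            raise ValueError("min_apf must be in [0, 1]")
        if self.n_rays < 8:
            raise ValueError("n_rays must be >= 8")
        if not 0 < self.perc_percentile < 100:
            raise ValueError("perc_percentile must be in (0, 100)")
        if not -1024 <= self.laa_threshold_hu <= 0:
            raise ValueError("laa_threshold_hu outside physical range")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str) -> None:
        """Write as a flat key=value text file."""
        with open(path, "w", encoding="utf-8") as fh:
            for k, v in self.to_dict().items():
                fh.write(f"{k}={v}\n")

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                key = key.strip()
                raw = raw.strip()
                if key not in fields:
                    raise KeyError(f"unknown config key {key!r}")
                kwargs[key] = _coerce(key, raw)
        return cls(**kwargs)


def _coerce(key: str, raw: str):
    if key in ("n_rays", "seed"):
        return int(raw)
    if key == "log_level":
        return raw
    if key == "hu_wall_ref" and raw == "auto":
        return raw
    return float(raw)
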