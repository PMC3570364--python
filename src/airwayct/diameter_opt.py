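"""Optimal fixed lumen diameter: the candidate maximizing cumulative APF.

Wall thickness standardized to a fixed internal lumen diameter is only
useful at a caliber where many airway locations are measurable.  Sweeping
candidate diameters (2.5-5.0 mm in 0.5 mm steps, each +/- 0.25 mm) and
summing the assessed perimeter fractions of the selected locations per
subject identifies that caliber; the optimum is the candidate with the
highest grand-mean cumulative APF (ties break toward the smaller, more
peripheral diameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .airway_quant import CrossSection, select_fixed_diameter_locations

DEFAULT_CANDIDATES = (2.5, 3.0, 3.5, 4.0, 4.5, 5.0)


@dataclass
class SweepResult:
    diameters_mm: tuple[float, ...]
    apf_cum: pd.DataFrame  # index: subject, columns: candidate diameter
    group_means: pd.DataFrame | None
    optimal_mm: float
    tol_mm: float = 0.25
    groups: dict = field(default_factory=dict)


def apf_sweep(
    sections_per_subject: dict[str, list[CrossSection]],
    candidates=DEFAULT_CANDIDATES,
    tol_mm: float = 0.25,
    min_apf: float = 0.25,
    groups: dict[str, str] | None = None,
) -> SweepResult:
    """Cumulative APF per subject at each candidate diameter.

    ``sections_per_subject`` maps a subject id to its measured
    cross-sections (all diameters); per candidate the fixed-diameter
    selection is re-applied and the local APFs of the retained locations
    summed.  Group means are reported when ``groups`` labels subjects.
    """
    if not sections_per_subject:
        raise ValueError("at least one subject is required")
    candidates = tuple(float(c) for c in candidates)
    if not candidates:
        raise ValueError("candidate list must not be empty")

    rows = {}
    for subj, sections in sections_per_subject.items():
        rows[subj] = {
            d: sum(
                loc.apf_local
                for loc in select_fixed_diameter_locations(
                    sections, d, tol_mm, min_apf
                )
            )
            for d in candidates
        }
    apf = pd.DataFrame.from_dict(rows, orient="index")[list(candidates)]

    group_means = None
    if groups:
        lab = pd.Series({s: groups.get(s, "all") for s in apf.index})
        group_means = apf.groupby(lab).mean()

    grand = apf.mean(axis=0)
    best = grand.max()
    # tie rule: smallest diameter among the maximizers
    optimal = min(d for d in candidates if np.isclose(grand[d], best))
    return SweepResult(
        diameters_mm=candidates,
        apf_cum=apf,
        group_means=group_means,
        optimal_mm=float(optimal),
        tol_mm=tol_mm,
        groups=dict(groups or {}),
    )
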