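"""End-to-end subject pipeline: volumes -> measurements -> metrics -> stats.

The manifest is a CSV with one row per subject:

========== ========================================================
column     meaning
========== ========================================================
subject_id unique id
ct         path to the CT volume (.nii/.nii.gz/.mha/.mhd)
labels     path to the label volume (same grid)
ct_high    optional second acquisition for dose-pair agreement
group      optional stratum label for the diameter sweep
========== ========================================================

Outputs: per-subject location and lobe CSVs, a subject metrics table, an
optional Bland-Altman agreement block (when dose pairs are present), and a
single JSON report embedding the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import airway_quant as aq
from .cohort_stats import bland_altman
from .config import RunConfig
from .emphysema_quant import densitometry
from .volume import read_labels, read_volume

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject!r}: {cause}")
        self.stage = stage
        self.subject = subject


def locations_frame(locations) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lobe": l.lobe,
                "generation": l.generation,
                "internal_diameter_mm": l.internal_diameter_mm,
                "awt_mm": l.awt_mm,
                "apf_local": l.apf_local,
                "branch_id": l.branch_id,
                "position_index": l.position_index,
            }
            for l in locations
        ]
    )


def lobes_frame(summaries: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lobe": s.lobe,
                "awt_mm": s.awt_mm,
                "apf_cum": s.apf_cum,
                "n_locations": s.n_locations,
            }
            for s in summaries.values()
        ]
    )


def measure_subject_files(ct_path, labels_path, config: RunConfig):
    """Measure one subject from files: returns (sections, locations,
    metrics) with densitometry attached."""
    ct = read_volume(ct_path)
    labels = read_labels(labels_path)
    sections, locations = aq.measure_airways(ct, labels=labels, config=config)
    # scenes without a trachea label cannot be recalibrated; densitometry
    # then runs on the raw HU values (the calibration shift stays 0)
    recalibrate = bool(labels.trachea_mask().any())
    if not recalibrate:
        logger.warning("no trachea label in %s: skipping HU recalibration",
                       labels_path)
    dens = densitometry(ct, labels, config, recalibrate=recalibrate)
    metrics = aq.subject_metrics(locations, dens)
    return sections, locations, metrics


def run_pipeline(config: RunConfig, manifest: pd.DataFrame, out_dir: str) -> dict:
    """Run measurement and densitometry over a manifest of subjects.

    Fully deterministic under ``config.seed``; any stage failure aborts
    with the stage name and subject id and leaves no partial report.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest: nothing to process")
    if "subject_id" not in manifest.columns:
        raise ValueError("manifest needs a subject_id column")
    os.makedirs(out_dir, exist_ok=True)

    subjects = []
    pairs = []
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        t0 = time.time()
        try:
            sections, locations, metrics = measure_subject_files(
                row["ct"], row["labels"], config
            )
        except Exception as e:  # noqa: BLE001 - rewrap with stage context
            raise StageError("measure", sid, e) from e
        logger.info("subject %s stage measure done in %.1fs", sid, time.time() - t0)

        locations_frame(locations).to_csv(
            os.path.join(out_dir, f"{sid}_locations.csv"), index=False
        )
        lobes_frame(metrics.lobes).to_csv(
            os.path.join(out_dir, f"{sid}_lobes.csv"), index=False
        )
        subjects.append(
            {
                "subject_id": sid,
                "awt35_mm": metrics.awt35_mm,
                "apf_total": metrics.apf_total,
                "n_locations": metrics.n_locations,
                "perc15_hu": metrics.perc15_hu,
                "laa950_pct": metrics.laa950_pct,
                "log_laa950": metrics.log_laa950,
                "lung_volume_l": metrics.lung_volume_l,
                "calibration_shift_hu": metrics.calibration_shift_hu,
            }
        )

        if "ct_high" in manifest.columns and isinstance(row.get("ct_high"), str) \
                and row["ct_high"]:
            try:
                _, _, metrics_high = measure_subject_files(
                    row["ct_high"], row["labels"], config
                )
            except Exception as e:  # noqa: BLE001
                raise StageError("measure_high_dose", sid, e) from e
            pairs.append((metrics.awt35_mm, metrics_high.awt35_mm))

    report: dict = {
        "config": dataclasses.asdict(config),
        "n_subjects": len(subjects),
        "subjects": subjects,
    }
    subj_df = pd.DataFrame(subjects)
    subj_df.to_csv(os.path.join(out_dir, "subjects.csv"), index=False)

    if pairs:
        arr = np.asarray(pairs)
        agreement = bland_altman(arr[:, 0], arr[:, 1])
        report["agreement"] = dataclasses.asdict(agreement)

    report_path = os.path.join(out_dir, "report.json")
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
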