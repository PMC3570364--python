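"""Shared fixtures: phantoms are rasterized once per session."""

from __future__ import annotations

import numpy as np
import pytest

from airwayct import (
    AcquisitionSpec,
    PhantomTruth,
    RunConfig,
    build_airway_tree,
    rasterize_phantom,
    single_tube_scene,
    tube_acquisition,
)
from airwayct.airway_quant import (
    centerlines_from_truth,
    extract_centerlines,
    measure_cross_sections,
)
from airwayct.cohort_sim import default_params, simulate_cohort


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def tube_bundle(config):
    """A single 3.5 mm lumen / 0.6 mm wall tube at protocol geometry,
    low-dose noise, measured with ground-truth centerlines."""
    branches, truth = single_tube_scene(3.5, 0.6, length_mm=40.0)
    acq = tube_acquisition(noise_sd_hu=25.0, seed=11)
    ct, labels = rasterize_phantom(branches, truth, acq)
    cl = centerlines_from_truth(branches)[0]
    sections = measure_cross_sections(ct, cl, config)
    return {
        "branches": branches,
        "truth": truth,
        "acq": acq,
        "ct": ct,
        "labels": labels,
        "centerline": cl,
        "sections": sections,
    }


@pytest.fixture(scope="session")
def tree_bundle(config):
    """Five-lobe airway tree with 5% emphysema at protocol voxel geometry,
    low-dose noise; centerlines extracted from the label volume."""
    branches = build_airway_tree("five-lobe", seed=1)
    truth = PhantomTruth(branches=branches, emphysema_fraction=0.05)
    acq = AcquisitionSpec(fov_mm=150.0, matrix=220, noise_sd_hu=25.0, seed=3)
    ct, labels = rasterize_phantom(branches, truth, acq)
    centerlines = extract_centerlines(labels)
    sections = []
    for cl in centerlines:
        sections.extend(measure_cross_sections(ct, cl, config))
    return {
        "branches": branches,
        "truth": truth,
        "acq": acq,
        "ct": ct,
        "labels": labels,
        "centerlines": centerlines,
        "sections": sections,
    }


@pytest.fixture(scope="session")
def cohort():
    return simulate_cohort(default_params(seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
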