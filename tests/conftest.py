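"""Shared fixtures: the synthetic scenes are expensive to render, so the
default scenes are session-scoped and analysed once."""

from __future__ import annotations

import numpy as np
import pytest

from nodule4d import blebmot, morpho, preproc, segment, spatial, synthgen

NODULE_SEED = 1
BLEB_SEED = 7


@pytest.fixture(scope="session")
def nodule_scene():
    """(stack, truth) for the default nodule time course."""
    return synthgen.generate_nodule_timecourse(seed=NODULE_SEED)


@pytest.fixture(scope="session")
def nodule_filtered(nodule_scene):
    stack, _ = nodule_scene
    return preproc.median_filter(stack, radius=1)


@pytest.fixture(scope="session")
def nodule_surfaces(nodule_filtered):
    return [
        segment.segment_shg(nodule_filtered, timepoint=t)
        for t in range(nodule_filtered.n_timepoints)
    ]


@pytest.fixture(scope="session")
def nodule_records0(nodule_filtered, nodule_surfaces):
    """Classified cell records at the first timepoint."""
    cells = segment.segment_cells(nodule_filtered, timepoint=0)
    recs = morpho.measure_cells(cells, timepoint=0)
    recs = morpho.classify_high_sphericity(recs)
    recs = spatial.classify_compartment(recs, nodule_surfaces[0])
    return recs


@pytest.fixture(scope="session")
def lacuna_spot_series(nodule_filtered, nodule_surfaces):
    """Detected lacuna spots at two timepoints (fixed true constellation)."""
    return [
        segment.extract_lacunae(nodule_filtered, timepoint=t, shg_mask=nodule_surfaces[t].mask)
        for t in (1, 3)
    ]


@pytest.fixture(scope="session")
def bleb_scene():
    """(stack, truth) for the default 2D bleb movie."""
    return synthgen.generate_bleb_movie(seed=BLEB_SEED)


@pytest.fixture(scope="session")
def bleb_tracks(bleb_scene):
    stack, _ = bleb_scene
    movie = stack.channel("EGFP")[:, 0]
    return blebmot.detect_blebs_2d(movie, stack.calibration)


@pytest.fixture(scope="session")
def bleb4d_scene():
    """(stack, truth) for the volumetric bleb movie with the
    lower-hemisphere exclusion zone."""
    return synthgen.generate_bleb_movie(synthgen.default_bleb4d_config(), seed=3)


@pytest.fixture(scope="session")
def bleb4d_spots(bleb4d_scene):
    stack, truth = bleb4d_scene
    hosts = {c.cell_id: c.centroid for c in truth.cells}
    radii = {c.cell_id: float(np.prod(c.semi_axes)) ** (1 / 3) for c in truth.cells}
    movie = stack.channel("EGFP")
    spots = blebmot.detect_blebs_4d(movie, stack.calibration, hosts, radii)
    return spots, hosts


@pytest.fixture(scope="session")
def bio_pair():
    """Treated and vehicle arms of the drug-response scenario, same seed."""
    treated = synthgen.generate_bio_experiment(synthgen.default_bio_config(True), seed=2)
    vehicle = synthgen.generate_bio_experiment(synthgen.default_bio_config(False), seed=2)
    return treated, vehicle


def tiny_nodule_config(**overrides) -> synthgen.SceneConfig:
    """A small, fast nodule configuration for pipeline-level tests."""
    import dataclasses

    cfg = synthgen.SceneConfig(
        shape=(3, 40, 192, 192),
        timepoints_days=(7.0, 10.0, 14.0),
        sphericity_schedule=(0.7026, 0.65, 0.55),
        growth=synthgen.GrowthParams(saturation_um3=15_000.0),
        n_cells_on=3,
        n_cells_off=0,
        cell_volume_um3=500.0,
        lacuna_per_um3=0.0,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg
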