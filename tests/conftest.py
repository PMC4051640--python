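"""Shared fixtures: a small analytic phantom for unit tests and one
session-scoped full pipeline run for the end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

from motormap import phantom
from motormap.workbench import PipelineConfig, run_phantom_case


def small_regions() -> dict[str, phantom.RegionDef]:
    """Minimal anatomy on a 24 x 24 x 20 grid for fast unit tests."""
    R = phantom.RegionDef
    return {
        "brain": R("ellipsoid", (11.5, 11.5, 9.5), (11.0, 11.0, 9.0)),
        "precentral_L": R("box", (6, 14, 10), (3, 1.5, 6)),
        "precentral_R": R("box", (17, 14, 10), (3, 1.5, 6)),
        "postcentral_L": R("box", (6, 9, 10), (3, 1.5, 6)),
        "postcentral_R": R("box", (17, 9, 10), (3, 1.5, 6)),
        "hand_knob_L": R("ellipsoid", (6, 11.5, 12), (2, 1, 2)),
        "hand_knob_R": R("ellipsoid", (17, 11.5, 12), (2, 1, 2)),
        "paracentral_L": R("box", (10, 12, 16), (1.5, 3, 2)),
        "paracentral_R": R("box", (13, 12, 16), (1.5, 3, 2)),
        "lesion": R("ellipsoid", (15, 17, 7), (2, 2, 2)),
        "white_matter": R("ellipsoid", (11.5, 11.5, 7), (4, 5, 3)),
    }


@pytest.fixture()
def small_spec() -> phantom.PhantomSpec:
    return phantom.PhantomSpec(
        grid_shape=(24, 24, 20), n_volumes=72, tr=2.0,
        regions=small_regions(), seed=7,
    )


@pytest.fixture()
def small_truth(small_spec):
    return phantom.make_phantom(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pipeline_record():
    """One full default-phantom pipeline run, shared across tests."""
    return run_phantom_case(PipelineConfig(seed=1))
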