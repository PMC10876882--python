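"""Shared fixtures: small synthetic cohorts generated once per session."""

import numpy as np
import pytest
from hypothesis import settings

import fastbold as fb

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: same structure as the default, smaller grid/length."""
    return fb.CohortConfig(
        n_young=3, n_old=3, n_volumes=600, grid_shape=(12, 12, 8),
        n_rois=21, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return fb.generate_cohort(small_config)


@pytest.fixture(scope="session")
def subject(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def pre_series(subject):
    """The subject's BOLD after the common high-pass step."""
    return fb.highpass(subject.bold, 0.01)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_series(values, tr=0.38, **kw):
    """Wrap a plain matrix in a VoxelTimeSeries with dummy coordinates."""
    values = np.atleast_2d(np.asarray(values, float))
    idx = np.zeros((values.shape[0], 3), dtype=int)
    idx[:, 0] = np.arange(values.shape[0])
    return fb.VoxelTimeSeries(values=values, tr=tr, voxel_index=idx, **kw)
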