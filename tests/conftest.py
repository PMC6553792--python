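"""Shared fixtures: expensive optics/mosaic objects built once per session."""

import pytest

from coneobserver import (
    ExperimentConfig,
    OpticsModel,
    SceneParams,
    build_mosaic,
    build_stimulus_maps,
)


@pytest.fixture(scope="session")
def scene_params():
    return SceneParams()


@pytest.fixture(scope="session")
def default_optics():
    return OpticsModel()


@pytest.fixture(scope="session")
def mosaic_default():
    """Reference mosaic: 1,560 cones/deg^2, 0.6:0.3:0.1, coverage 0.49."""
    return build_mosaic(seed=101)


@pytest.fixture(scope="session")
def mosaic_small():
    """Low-density mosaic (43 x 43), cheap enough for classifier tests."""
    return build_mosaic(density_deg2=466.0, coverage="auto", seed=102)


@pytest.fixture(scope="session")
def maps_default(scene_params, default_optics):
    """Unit-aperture stimulus maps for the default scene and optics."""
    return build_stimulus_maps(scene_params, default_optics)


@pytest.fixture(scope="session")
def small_config():
    """Low-density, few-trial experiment configuration for pipeline tests."""
    return ExperimentConfig(
        contrast_levels=[0.0, 0.01, 0.03, 0.06, 0.10],
        trials_per_contrast=40,
        n_repeats=1,
        density_deg2=466.0,
        coverage="auto",
        folds=10,
        master_seed=7,
    )
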