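"""Shared fixtures: one instrument grid, the default endmember set, and a
handful of pre-rendered synthetic scenes reused across test modules."""

import numpy as np
import pytest

from qramanomics import PreprocessConfig
from qramanomics import synthetic as syn
from qramanomics.preprocess import crop_and_mask, preprocess_stack


@pytest.fixture(scope="session")
def axis():
    return syn.make_axis()


@pytest.fixture(scope="session")
def models():
    return syn.default_peak_models()


@pytest.fixture(scope="session")
def model_by_name(models):
    return {m.name: m for m in models}


@pytest.fixture(scope="session")
def blank(axis):
    return syn.simulate_blank(axis)


@pytest.fixture(scope="session")
def config():
    return PreprocessConfig()


@pytest.fixture(scope="session")
def library(models, axis, config):
    """The analytic unit-scaled reference library on the cropped grid."""
    return syn.reference_library_from_models(models, axis, config)


@pytest.fixture(scope="session")
def drug_reference(axis, config):
    s = syn.make_component_spectrum(syn.drug_peak_model(), axis)
    return crop_and_mask(s, config.crop_window, config.silent_mask)


@pytest.fixture(scope="session")
def noiseless_scene(models, blank, config):
    """A small noiseless organoid scene preprocessed end to end."""
    truth = syn.make_organoid_truth(shape=(3, 8, 8), seed=11)
    stack = syn.simulate_organoid_stack(truth, models)
    pre = preprocess_stack(stack, blank, config, branch=532)
    return truth, stack, pre


@pytest.fixture(scope="session")
def snr20_scene(models, blank, config):
    """The noisy recovery scene: 6 components, mean voxel SNR 20."""
    truth = syn.make_organoid_truth(shape=(5, 20, 20), seed=42)
    quiet = syn.simulate_organoid_stack(truth, models)
    truth.noise_sd = syn.noise_sd_for_snr(quiet, 20.0)
    stack = syn.simulate_organoid_stack(truth, models)
    pre = preprocess_stack(stack, blank, config, branch=532)
    return truth, stack, pre


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
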