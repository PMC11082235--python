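"""Shared fixtures: trained classifiers and a rendered default experiment.

All heavy objects are session-scoped and seeded, so every test sees the same
models and imagery and the whole suite stays within a desk-scale budget.
"""

import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from artseqfish import simulate as sim
from artseqfish.cell_reconstruction import train_single_nucleus_classifier
from artseqfish.nucleus_segmentation import train_label_quality_classifier
from artseqfish.spot_detection import detect_spots, train_psf_classifier


@pytest.fixture(scope="session")
def psf_classifier():
    pos, neg = sim.make_psf_training_patches(n_pos=1000, n_neg=1000, seed=0)
    return train_psf_classifier(pos, neg, seed=0)


@pytest.fixture(scope="session")
def label_classifier():
    good, bad = sim.make_mask_training_set(n_good=300, n_bad=300, seed=1)
    return train_label_quality_classifier(good, bad, seed=1)


@pytest.fixture(scope="session")
def single_nucleus_classifier():
    singles, multis = sim.make_nucleus3d_training_set(n_single=150, n_multi=150, seed=2)
    return train_single_nucleus_classifier(singles, multis, seed=2)


@pytest.fixture(scope="session")
def default_experiment():
    """One rendered default-density experiment with its ground truth."""
    cfg = sim.SimulationConfig(seed=1)
    stack, truth = sim.render_experiment(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def default_detections(default_experiment, psf_classifier):
    _cfg, stack, _truth = default_experiment
    return detect_spots(stack, psf_classifier, min_distance=1)


@pytest.fixture(scope="session")
def zero_noise_experiment():
    cfg = sim.SimulationConfig(seed=4, poisson_noise=False, read_noise_sigma=0.0)
    stack, truth = sim.render_experiment(cfg)
    return cfg, stack, truth
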