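"""Shared fixtures: fixture datasets and (session-scoped) trained minis."""

import numpy as np
import pytest

from synthex import classifier_core, fixtures, generator_core
from synthex.cli import make_fixture_dataset


@pytest.fixture(scope="session")
def texture_dataset():
    """400 labelled fixture tiles (200 per class) at 32 px."""
    return make_fixture_dataset(200, 32, seed=1)


@pytest.fixture(scope="session")
def trained_classifier(texture_dataset):
    """Mini classifier trained on 80% of the texture dataset."""
    images, labels = texture_dataset
    split = int(0.8 * len(images))
    cfg = classifier_core.ClassifierConfig(
        steps=300, seed=1, augment=classifier_core.AugmentConfig()
    )
    model = classifier_core.train_classifier(images[:split], labels[:split], cfg)
    model.holdout = (images[split:], labels[split:])
    return model


@pytest.fixture(scope="session")
def trained_gan(texture_dataset):
    """Mini cGAN trained for 12 kimg on the texture dataset."""
    images, labels = texture_dataset
    cfg = generator_core.GANTrainConfig(total_kimg=12.0, seed=1,
                                        fid_interval_kimg=12.0)
    return generator_core.train_mini_cgan((images, labels), cfg)


@pytest.fixture(scope="session")
def analytic_generator():
    return fixtures.AnalyticGenerator()


@pytest.fixture(scope="session")
def oracle_classifier():
    return fixtures.OracleClassifier()
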