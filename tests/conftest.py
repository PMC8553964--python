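"""Shared fixtures: synthetic cohorts reused by the heavier tests."""

import numpy as np
import pytest

from hfopipe.detector import sample_balanced
from hfopipe.pipeline import build_feature_images, simulate_labeled_epochs
from hfopipe.synth import SimConfig


@pytest.fixture(scope="session")
def ripple_cohort_epochs():
    """Amplitude-separated ripple cohort (EZ 60 µV vs non-EZ 30 µV), 300/class.

    Epochs are extracted at ground-truth event centers; the detector has
    its own dedicated recovery tests.
    """
    cfg = SimConfig(duration_s=1500, n_channels=1, ripple_rate=40,
                    ez_amp_mean=60.0, nonez_amp_mean=30.0, amp_sd=10.0,
                    spike_rate=0.0, seed=42)
    epochs = simulate_labeled_epochs(cfg, "ripple", use_detector=False)
    return sample_balanced(epochs, 300, seed=0)


@pytest.fixture(scope="session")
def ripple_aspwvd_fixed(ripple_cohort_epochs):
    """Fixed-scale (cohort-adjusted) ASPWVD images of the ripple cohort."""
    return build_feature_images(ripple_cohort_epochs, "spwvd", "fixed")


@pytest.fixture(scope="session")
def fr_cohort_epochs():
    """Amplitude-separated fast-ripple cohort, 150/class."""
    cfg = SimConfig(duration_s=800, n_channels=1, ripple_rate=0.0, fr_rate=40,
                    ez_amp_mean=60.0, nonez_amp_mean=30.0, amp_sd=10.0,
                    spike_rate=0.0, seed=7)
    epochs = simulate_labeled_epochs(cfg, "fr", use_detector=False)
    return sample_balanced(epochs, 150, seed=0)
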