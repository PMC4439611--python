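"""Shared fixtures: phantoms and preprocessed pipeline stages.

Expensive stages (SRAD, Hough, homomorphic) are computed once per
session on the standard test slice and reused across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import boneseg as bs
from boneseg.phantom import BiasSpec, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def std_phantom():
    """Standard noisy, biased normal phantom (Rician sigma = 10% of the
    head intensity, bias amplitude 0.3)."""
    return make_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and bias-free normal phantom."""
    return make_phantom(PhantomSpec(seed=5, noise_sigma=0,
                                    bias=BiasSpec(amplitude=0)))


@pytest.fixture(scope="session")
def std_pipeline_stages(std_phantom):
    """(denoised, roi, corrected) for the standard phantom."""
    img, _ = std_phantom
    den = bs.srad(img)
    roi = bs.detect_humeral_circle(den)
    corr = bs.homomorphic_correct(den)
    return den, roi, corr


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
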