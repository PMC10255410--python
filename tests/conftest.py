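"""Shared fixtures: random SPD batches and synthetic covariance sets."""

import numpy as np
import pytest

from riemanneeg import smr_synth


def random_spd(rng: np.random.Generator, n: int, cond: float = 10.0) -> np.ndarray:
    """Random SPD matrix with controlled conditioning."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    w = np.exp(rng.uniform(0, np.log(cond), n))
    return (Q * w) @ Q.T


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def spd_batch(rng):
    """Eight random 4x4 SPD matrices."""
    return np.stack([random_spd(rng, 4) for _ in range(8)])


@pytest.fixture(scope="session")
def separated_covs():
    """Well-separated 8-channel synthetic subject (fast classifier workhorse)."""
    cfg = smr_synth.SynthConfig(n_channels=8, seed=7, separation=3.0, noise_df=640)
    covs, cms = smr_synth.make_covariance_set(cfg)
    return covs, cms


@pytest.fixture(scope="session")
def small_subject_runs():
    """One 8-channel synthetic subject's runs (both natures)."""
    cfg = smr_synth.SynthConfig(n_channels=8, seed=3, separation=1.0)
    return smr_synth.generate_subject(cfg), cfg
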