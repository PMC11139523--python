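"""Shared fixtures: tiny planted cohorts and fast training configs.

All fixtures are generated programmatically from fixed seeds; no data files
are read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from sigxae import (
    SBSCatalogue,
    XAEConfig,
    generate_cohort,
    generate_signatures,
)
from sigxae.simulate import ScenarioSpec, SubcohortSpec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_516)


def tiny_xae(k: int, **overrides) -> XAEConfig:
    """Small, quick training configuration for unit tests."""
    defaults = dict(
        latent_dim=k, encoder_units=(32, 24, 16), batch_size=16,
        learning_rate=7e-3, max_epochs=200, patience=50,
        validation_fraction=0.1, latent_batchnorm=True, seed=0,
    )
    defaults.update(overrides)
    return XAEConfig(**defaults)


@pytest.fixture()
def tiny_xae_factory():
    return tiny_xae


def planted_cohort(k: int, m: int, burden: float, seed: int = 0,
                   max_cos: float = 0.5, log_sd: float = 0.3):
    """A small cohort with k well-separated planted signatures.

    Every signature is active in every sample (prevalence 1) so exposures
    vary smoothly; returns (catalogue, ground truth, signature matrix).
    """
    sigs = generate_signatures(k, max_pairwise_cosine=max_cos, seed=seed)
    spec = ScenarioSpec(
        subcohorts=[SubcohortSpec("all", m, list(range(k)),
                                  prevalences=[1.0] * k)],
        burden_log_mean=float(np.log(burden)),
        burden_log_sd=log_sd,
        seed=seed + 1,
    )
    catalogue, truth = generate_cohort(spec, sigs)
    return catalogue, truth, sigs


@pytest.fixture()
def planted_cohort_factory():
    return planted_cohort


@pytest.fixture(scope="session")
def rank1_catalogue():
    """Noise-free rank-1 catalogue: every row proportional to one profile."""
    profile = generate_signatures(1, seed=4).profiles[:, 0]
    rows = np.rint(1000 * np.tile(profile, (50, 1))).astype(int)
    return SBSCatalogue(rows, [f"S{i}" for i in range(50)]), profile
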