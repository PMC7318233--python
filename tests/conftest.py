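"""Shared fixtures: synthetic cohorts with known latent structure."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import symptomnet as sn


@pytest.fixture(scope="session")
def matching_structure():
    """Disjoint-pair precision benchmark (identifiable edge recovery)."""
    K, edges = sn.make_matching_precision(10, weight=0.35)
    return K, sn.latent_from_precision(K), edges


@pytest.fixture(scope="session")
def matching_cohort(matching_structure):
    _, R, _ = matching_structure
    spec = sn.GeneratorSpec(
        n=5000, prevalences=[0.5] * 10, latent_correlation=R, seed=1
    )
    return sn.generate(spec)


@pytest.fixture(scope="session")
def hub_chain_structure():
    """Hub-plus-chain precision benchmark (differentiated node strengths)."""
    K, edges = sn.make_hub_chain_precision(10)
    return K, sn.latent_from_precision(K), edges


@pytest.fixture(scope="session")
def hub_chain_cohort(hub_chain_structure):
    _, R, _ = hub_chain_structure
    spec = sn.GeneratorSpec(
        n=5000, prevalences=[0.5] * 10, latent_correlation=R, seed=7
    )
    return sn.generate(spec)


@pytest.fixture(scope="session")
def hub_chain_network(hub_chain_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sn.estimate_network(hub_chain_cohort)


@pytest.fixture(scope="session")
def noise_cohort():
    """Latently independent items: no true edges, no stable ordering."""
    spec = sn.GeneratorSpec(
        n=200, prevalences=[0.5] * 10, latent_correlation=np.eye(10), seed=5
    )
    return sn.generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
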