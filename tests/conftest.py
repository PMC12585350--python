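"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import stepgrad as sg

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def brute_force_walks(adjacency: np.ndarray, seed: int, max_step: int) -> np.ndarray:
    """Independent oracle: count walks by exhaustive recursive enumeration.

    Enumerates every node sequence (seed, v1, ..., vx) along edges; the
    count for (step x, target j) is the number of sequences ending at j.
    Exponential in max_step; only usable on tiny graphs.
    """
    n = adjacency.shape[0]
    counts = np.zeros((max_step, n), dtype=np.int64)

    def extend(node: int, depth: int):
        for nxt in range(n):
            if adjacency[node, nxt]:
                counts[depth, nxt] += 1
                if depth + 1 < max_step:
                    extend(nxt, depth + 1)

    extend(seed, 0)
    return counts


def make_atlas(n: int, n_networks: int = 1) -> sg.ROIAtlas:
    """Minimal valid atlas: alternating hemispheres, one seed per side."""
    hemi = np.array(["left" if i % 2 == 0 else "right" for i in range(n)], dtype=object)
    labels = [f"net{j}" for j in range(n_networks)]
    network = np.array([labels[i * n_networks // n] for i in range(n)], dtype=object)
    is_seed = np.zeros(n, dtype=bool)
    is_seed[0] = True
    if n > 1:
        is_seed[1] = True
    return sg.ROIAtlas(
        names=tuple(f"roi{i}" for i in range(n)),
        hemisphere=hemi,
        network=network,
        is_seed=is_seed,
    )


def make_functional(matrix: np.ndarray, atlas=None) -> sg.Connectome:
    m = np.asarray(matrix, dtype=float)
    atlas = atlas or make_atlas(m.shape[0])
    return sg.Connectome(modality="functional", matrix=m, atlas=atlas)


def random_correlation_connectome(n: int, rng: np.random.Generator, atlas=None):
    """Valid random functional connectome from random time series."""
    x = rng.standard_normal((n, 4 * n))
    c = np.corrcoef(x)
    np.fill_diagonal(c, 0.0)
    return make_functional(c, atlas)


@pytest.fixture(scope="session")
def default_config() -> sg.SimulationConfig:
    return sg.SimulationConfig(rng_seed=0)


@pytest.fixture(scope="session")
def default_cohort(default_config) -> sg.CohortTable:
    """The default synthetic cohort (planted CI effects), shared across tests."""
    return sg.simulate_cohort(default_config)


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """Full left-hemisphere functional analysis of the default cohort."""
    return sg.run_analysis(default_cohort, n_perm=1000, rng_seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
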