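"""Shared fixtures: small synthetic studies reused across test modules.

Heavy simulated objects are session-scoped; tests must not mutate them.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import reomap
from reomap.session import compute_session_tables


@pytest.fixture(scope="session")
def day1_config() -> reomap.SimConfig:
    """One animal, one day, 20 FI + 5 FS cells, default noise."""
    return reomap.SimConfig(
        n_animals=1, n_days=1, n_fi_cells=20, n_fs_cells=5,
        coherence_by_day=(0.75,), rate_gain_by_day=(1.0,),
        dig_probs_by_day=((0.375, 0.375, 0.125, 0.125),),
        trial_duration_s=120.0, seed=101,
    )


@pytest.fixture(scope="session")
def day1_bundle(day1_config) -> reomap.SessionBundle:
    return reomap.generate_study(day1_config)[0]


@pytest.fixture(scope="session")
def day1_tables(day1_bundle):
    return compute_session_tables(day1_bundle)


@pytest.fixture(scope="session")
def clean_bundle() -> reomap.SessionBundle:
    """Fully coherent, noise-free session: every cell follows the ensemble
    orientation exactly and digs follow orientation deterministically."""
    cfg = reomap.SimConfig(
        n_animals=1, n_days=1, n_fi_cells=10, n_fs_cells=3,
        coherence_by_day=(1.0,), rate_gain_by_day=(1.0,),
        dig_probs_by_day=((0.5, 0.5, 0.0, 0.0),),
        p_dig_follows_orientation=1.0, noise_rate_hz=0.0,
        trial_duration_s=120.0, seed=202,
    )
    return reomap.generate_study(cfg)[0]


@pytest.fixture(scope="session")
def clean_tables(clean_bundle):
    return compute_session_tables(clean_bundle)


@pytest.fixture(scope="session")
def three_day_study():
    """Two animals over three days with the default learning schedules."""
    cfg = reomap.SimConfig(
        n_animals=2, n_days=3, n_fi_cells=20, n_fs_cells=5,
        trial_duration_s=120.0, seed=303,
    )
    bundles = reomap.generate_study(cfg)
    tables = [compute_session_tables(b) for b in bundles]
    return cfg, bundles, tables


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def replace_seed(cfg: reomap.SimConfig, seed: int) -> reomap.SimConfig:
    return dataclasses.replace(cfg, seed=seed)
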