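"""Shared fixtures.

The heavy session-scoped fixture ``scenario_runs`` simulates the full
canonical learning scenario (24 regions, 600 trials, learning-modulated
effects) for 20 independent seeds and decodes the complete region x
window x phase grid for each; several decoding properties and the
parameter-recovery check all read from it, so it is computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from megcat import (
    NoiseParams,
    compare_phases,
    decode_grid,
    default_layout,
    default_scenario_effects,
    generate_stimulus_set,
    make_prototype_pair,
    pool_pathways,
    remove_baseline,
    simulate_region_ensembles,
    simulate_sensor_epochs,
    sliding_average,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pair():
    return make_prototype_pair(seed=7)


@pytest.fixture(scope="session")
def small_stimuli(pair):
    """60-trial stimulus set (30 per category, 5 blocks of 12)."""
    return generate_stimulus_set(pair, 30, np.random.default_rng(11))


@pytest.fixture()
def noise_sensor_epochs(small_stimuli, rng):
    """Noise-only 16-channel sensor epochs for the small stimulus set."""
    return simulate_sensor_epochs(small_stimuli, [], NoiseParams(), rng, n_channels=16)


@pytest.fixture()
def noise_binned(noise_sensor_epochs):
    return sliding_average(remove_baseline(noise_sensor_epochs))


def simulate_scenario(seed: int):
    """One full canonical-scenario subject: region epochs, baseline-removed."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2024]))
    pair = make_prototype_pair(seed)
    stimuli = generate_stimulus_set(pair, 300, rng)
    layout = default_layout()
    regions = simulate_region_ensembles(
        stimuli, layout, default_scenario_effects(layout), NoiseParams(), rng
    )
    return {name: remove_baseline(ep) for name, ep in regions.items()}, layout


@pytest.fixture(scope="session")
def scenario_runs():
    """Decoding results of the canonical scenario for 20 independent seeds."""
    runs = []
    for seed in range(20):
        regions, layout = simulate_scenario(seed)
        table = decode_grid(regions, layout=layout)
        runs.append(
            {
                "table": table,
                "phase_comparison": compare_phases(table),
                "pooled": pool_pathways(table, layout),
            }
        )
    return runs
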