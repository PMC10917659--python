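"""Shared fixtures: synthetic probes and hand-built maps.

Expensive synthetic recordings are generated once per session and shared;
tests that need isolation build their own small fixtures.
"""

import numpy as np
import pytest

import spectrolaminar as sl


def relative_map(rec, n_out=24):
    """Recording -> standardized relative power map (the FLIP input)."""
    pmap = sl.compute_power_map(rec)
    return sl.standardize_depth(sl.relative_power(pmap), n_out)


@pytest.fixture(scope="session")
def default_probe():
    """One default synthetic probe: (recording, ground truth)."""
    return sl.generate_probe(sl.SyntheticProbeSpec(seed=1))


@pytest.fixture(scope="session")
def default_map(default_probe):
    rec, _truth = default_probe
    return relative_map(rec)


@pytest.fixture(scope="session")
def small_population():
    """Ten default probes with jittered laminar parameters."""
    return sl.generate_population(10, seed=42)


@pytest.fixture(scope="session")
def small_population_maps(small_population):
    return [relative_map(rec) for rec, _ in small_population]


@pytest.fixture()
def opposing_profiles():
    """Perfect opposing linear gradients over 24 channels."""
    n = 24
    p_ab = np.linspace(0.2, 1.0, n)
    p_g = np.linspace(1.0, 0.2, n)
    return p_ab, p_g


@pytest.fixture()
def simple_power_map():
    """4 channels x 5 frequency bins, all positive, distinct columns."""
    power = np.array([
        [2.0, 1.0, 5.0, 1.0, 3.0],
        [4.0, 2.0, 5.0, 2.0, 3.0],
        [8.0, 4.0, 5.0, 3.0, 3.0],
        [6.0, 3.0, 5.0, 4.0, 3.0],
    ])
    return sl.PowerMap(power=power, freqs=np.arange(1.0, 6.0))
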