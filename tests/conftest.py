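import math

import numpy as np
import pytest

import dnarray as da


@pytest.fixture(scope="session")
def hex_lattice():
    return da.build_lattice("hex", 2.8, math.sqrt(3.0), 4, 4)


@pytest.fixture(scope="session")
def hex5():
    return da.build_lattice("hex", 1.0, math.sqrt(3.0), 5, 5)


@pytest.fixture(scope="session")
def orto5():
    return da.build_lattice("orto", 1.0, 1.43, 5, 5)


@pytest.fixture(scope="session")
def frozen_array(hex_lattice):
    """Array with zero positional/azimuthal noise."""
    params = da.ArrayFluctuationParams(
        lattice=hex_lattice, sigma_pos=0.0, sigma_phi=0.0,
        preferred_delta_phi=2 * math.pi / 3, n_frames=5, seed=0)
    return da.gen_array(params)


@pytest.fixture(scope="session")
def noisy_array(hex_lattice):
    """Array with known Gaussian positional and azimuthal noise (2000 frames)."""
    params = da.ArrayFluctuationParams(
        lattice=hex_lattice, sigma_pos=0.05 * hex_lattice.a, sigma_phi=0.1,
        preferred_delta_phi=2 * math.pi / 3, screw_coupling=True,
        n_frames=2000, seed=42)
    return da.gen_array(params)


@pytest.fixture(scope="session")
def water_pair(hex_lattice):
    """Waters between the first NN pair with an imposed eta1 profile."""
    shell = da.first_neighbor_shell(hex_lattice)
    i1, i2 = shell.pairs[0]
    params = da.WaterProfileParams(
        pair_axis=(i1, i2), n_water=400, eta1_surface=0.5,
        decay_length=0.2, n_frames=60, seed=5)
    return da.gen_water_between_pair(params, hex_lattice), (i1, i2)
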