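"""Shared fixtures: synthetic cells, segmented models and passive specs."""

from dataclasses import replace

import numpy as np
import pytest

from rgcstim import (CableModel, MembraneSpec, extend_axon, generate_rgc,
                     segmentize)
from rgcstim.channels import RegionConductances


@pytest.fixture(scope="session")
def large_cell_morph():
    """Standard large-field synthetic RGC (191 um field, 900 um axon)."""
    return extend_axon(generate_rgc(191.0, seed=1), 900.0)


@pytest.fixture(scope="session")
def large_cell(large_cell_morph):
    return segmentize(large_cell_morph)


@pytest.fixture(scope="session")
def model(large_cell):
    m = CableModel(large_cell)
    m.rest_state()  # warm the cache once per session
    return m


@pytest.fixture(scope="session")
def small_cell():
    """Compact cell for solver comparisons (fits a dense solve comfortably)."""
    return segmentize(extend_axon(generate_rgc(120.0, seed=2, axon_length=100.0), 0.0))


@pytest.fixture(scope="session")
def passive_spec():
    """Leak-only membrane with a fast (2 ms) time constant for settling tests."""
    spec = MembraneSpec.default()
    return replace(spec, regions={r: RegionConductances(0, 0, 0, 0, 0, gl=0.5)
                                  for r in spec.regions})


@pytest.fixture(scope="session")
def midget_cell_morph():
    return generate_rgc(50.0, midget=True, seed=3)
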