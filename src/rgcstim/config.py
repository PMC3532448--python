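"""YAML configuration for stimulation/scan protocols and generator settings."""

from __future__ import annotations

import yaml

from .channels import MembraneSpec
from .field import ElectrodeSpec, InhomogeneityProfile, PulseSpec
from .cable import SimulationConfig
from .thresholds import ScanGrid

__all__ = ["load_config", "StudyConfig"]


class StudyConfig:
    """Bundle of parsed configuration sections (missing sections -> defaults)."""

    def __init__(self, electrode=None, pulse=None, profile=None,
                 simulation=None, grid=None, membrane=None, generator=None):
        self.electrode = electrode
        self.pulse = pulse or PulseSpec(amplitude=1.0)
        self.profile = profile
        self.simulation = simulation or SimulationConfig()
        self.grid = grid
        self.membrane = membrane or MembraneSpec.default()
        self.generator = generator or {}


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw = {}
    if "electrode" in raw:
        kw["electrode"] = ElectrodeSpec(**raw["electrode"])
    if "pulse" in raw:
        kw["pulse"] = PulseSpec(**raw["pulse"])
    if "inhomogeneity" in raw:
        kw["profile"] = InhomogeneityProfile(**raw["inhomogeneity"])
    if "simulation" in raw:
        kw["simulation"] = SimulationConfig(**raw["simulation"])
    if "grid" in raw:
        kw["grid"] = ScanGrid(**raw["grid"])
    if "membrane" in raw:
        kw["membrane"] = MembraneSpec.from_dict(raw["membrane"])
    if "generator" in raw:
        kw["generator"] = dict(raw["generator"])
    return StudyConfig(**kw)
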