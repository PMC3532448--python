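"""Population-level stimulation of RGC mosaics.

Cells in the mosaic are electrically independent: each experiences the same
imposed extracellular field at its own location, and a cell counts as
activated when its somatic Vm crosses 0 mV within the 40 ms window.  The
population threshold at a position is the minimum current that activates one
or more cells; it equals the minimum of the per-cell thresholds within the
search tolerance.  Because the field is evaluated in the electrode frame,
simulating a translated cell is equivalent to translating the electrode, so a
single cable model serves the whole mosaic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed
from shapely.geometry import MultiLineString, Point

from .cable import CableModel, FieldStimulus, SimulationConfig
from .field import ElectrodeSpec, InhomogeneityProfile, PulseSpec
from .mosaic import Mosaic
from .thresholds import (DEFAULT_CAP, DEFAULT_START, detect_spikes,
                         evoked_spikes, latency)

__all__ = [
    "CellActivation",
    "ActivationResult",
    "RecruitmentCurve",
    "PopulationMaps",
    "activated_cells",
    "population_threshold",
    "population_maps",
    "nearest_axon_distance",
    "suprathreshold_sweep",
]


@dataclass
class CellActivation:
    cell_id: int
    latency_ms: float
    initiation_comp: int
    initiation_region: str


@dataclass
class ActivationResult:
    """Activated cells at one position and amplitude."""

    amplitude: float
    activations: list = field(default_factory=list)

    @property
    def cell_ids(self) -> tuple:
        return tuple(sorted(a.cell_id for a in self.activations))

    def __len__(self) -> int:
        return len(self.activations)


def _simulate_cell(model: CableModel, mosaic: Mosaic, cell_id: int,
                   electrode: ElectrodeSpec, amplitude: float,
                   pulse: PulseSpec, profile, config) -> CellActivation | None:
    offset = next(c for c in mosaic.cells if c.cell_id == cell_id).offset
    # field in the cell frame: shift the electrode instead of the cell
    shifted = replace(electrode, x=electrode.x - offset[0],
                      y=electrode.y - offset[1])
    stim = FieldStimulus(shifted, replace(pulse, amplitude=amplitude), profile)
    trace = model.run(config, stimulus=stim)
    peaks = evoked_spikes(detect_spikes(trace.t, trace.soma), pulse)
    lat = latency(pulse.onset_ms, peaks)
    if len(peaks) == 0 or not np.isfinite(lat):
        return None
    fc = trace.first_cross_ms
    init = int(np.nanargmin(fc))
    return CellActivation(cell_id, lat, init, str(model.cell.region[init]))


def activated_cells(model: CableModel, mosaic: Mosaic, electrode: ElectrodeSpec,
                    amplitude: float, *, pulse: PulseSpec | None = None,
                    profile: InhomogeneityProfile | None = None,
                    config: SimulationConfig | None = None) -> ActivationResult:
    """Simulate every cell in the shared field; all mosaic cells considered."""
    pulse = pulse or PulseSpec(amplitude=1.0)
    config = config or SimulationConfig(duration=40.0)
    result = ActivationResult(amplitude=amplitude)
    if amplitude <= 0:
        return result
    for cell in mosaic.cells:
        act = _simulate_cell(model, mosaic, cell.cell_id, electrode, amplitude,
                             pulse, profile, config)
        if act is not None:
            result.activations.append(act)
    return result


def population_threshold(model: CableModel, mosaic: Mosaic,
                         electrode: ElectrodeSpec, *,
                         tolerance: float | None = None,
                         pulse: PulseSpec | None = None,
                         profile: InhomogeneityProfile | None = None,
                         config: SimulationConfig | None = None,
                         i_start: float = DEFAULT_START,
                         i_cap: float = DEFAULT_CAP):
    """Binary search on |activated cells| >= 1 at one electrode position.

    Returns (threshold_uA, ActivationResult at the spiking upper bracket);
    threshold is nan with an empty activation set when the cap is reached.
    """
    if len(mosaic) == 0:
        raise ValueError("mosaic is empty")
    if tolerance is None:
        tolerance = 0.1 if electrode.radius <= 10.0 else 0.5
    pulse = pulse or PulseSpec(amplitude=1.0)
    config = config or SimulationConfig(duration=40.0)

    def probe(amp):
        return activated_cells(model, mosaic, electrode, amp, pulse=pulse,
                               profile=profile, config=config)

    hi = i_start
    res = probe(hi)
    while len(res) == 0:
        if hi >= i_cap:
            return float("nan"), ActivationResult(amplitude=float("nan"))
        hi = min(2.0 * hi, i_cap)
        res = probe(hi)
    lo = 0.0 if hi == i_start else hi / 2.0
    best = res
    while hi - lo > tolerance:
        mid = 0.5 * (hi + lo)
        res = probe(mid)
        if len(res) > 0:
            hi, best = mid, res
        else:
            lo = mid
    # the activated set "at threshold" is the spiking upper bracket
    return hi, best


@dataclass
class PopulationMaps:
    """Per-position population threshold, activation counts and identities."""

    positions: np.ndarray
    threshold: np.ndarray
    counts: np.ndarray
    identities: list        # sorted cell-id tuples per position
    latencies: list         # dict cell_id -> latency per position
    electrode_radius: float

    def count_histogram(self) -> dict:
        vals, cnts = np.unique(self.counts[self.counts > 0], return_counts=True)
        return dict(zip(vals.tolist(), cnts.tolist()))

    def single_cell_fraction(self) -> float:
        ok = self.counts > 0
        if not ok.any():
            return float("nan")
        return float(np.mean(self.counts[ok] == 1))

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "x_um": self.positions[:, 0], "y_um": self.positions[:, 1],
            "threshold_ua": self.threshold, "n_active": self.counts,
            "cell_ids": ["|".join(map(str, ids)) for ids in self.identities],
        })


def _pop_one(model, mosaic, pos, radius, z, kwargs):
    electrode = ElectrodeSpec(radius=radius, x=pos[0], y=pos[1], z=z)
    thr, act = population_threshold(model, mosaic, electrode, **kwargs)
    return thr, act


def population_maps(model: CableModel, mosaic: Mosaic, grid,
                    electrode_radius: float, *, n_jobs: int = 1,
                    **kwargs) -> PopulationMaps:
    """Population threshold and activated-identity map over a scan grid."""
    positions = grid.positions()
    if n_jobs == 1:
        results = [_pop_one(model, mosaic, p, electrode_radius, grid.z, kwargs)
                   for p in positions]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_pop_one)(model, mosaic, p, electrode_radius, grid.z, kwargs)
            for p in positions)
    thr = np.array([r[0] for r in results])
    counts = np.array([len(r[1]) for r in results])
    idents = [r[1].cell_ids for r in results]
    lats = [{a.cell_id: a.latency_ms for a in r[1].activations} for r in results]
    return PopulationMaps(positions=positions, threshold=thr, counts=counts,
                          identities=idents, latencies=lats,
                          electrode_radius=electrode_radius)


def nearest_axon_distance(position, mosaic: Mosaic) -> float:
    """In-plane Euclidean distance from a point to the nearest axon polyline."""
    lines = [np.asarray(poly) for poly in mosaic.axon_polylines().values()
             if len(poly) >= 2]
    if not lines:
        return float("nan")
    geom = MultiLineString([line.tolist() for line in lines])
    return float(Point(float(position[0]), float(position[1])).distance(geom))


@dataclass
class RecruitmentCurve:
    """Activated sets under 1-3x threshold scaling at one position."""

    position: np.ndarray
    threshold: float
    multipliers: np.ndarray
    results: list  # ActivationResult per multiplier

    def counts(self) -> np.ndarray:
        return np.array([len(r) for r in self.results])

    def nested(self) -> bool:
        """Activated identity sets are supersets as the stimulus grows."""
        sets = [set(r.cell_ids) for r in self.results]
        return all(a <= b for a, b in zip(sets[:-1], sets[1:]))


def suprathreshold_sweep(model: CableModel, mosaic: Mosaic,
                         electrode: ElectrodeSpec,
                         multipliers=(1.0, 1.5, 2.0, 2.5, 3.0),
                         **kwargs) -> RecruitmentCurve:
    """Activated sets at multiples of the position's population threshold.

    Initiation-compartment labels record whether newly recruited cells were
    activated via their passing axons.
    """
    thr, base = population_threshold(model, mosaic, electrode, **kwargs)
    if not np.isfinite(thr):
        raise ValueError("position is not excitable below the cap")
    pulse = kwargs.get("pulse") or PulseSpec(amplitude=1.0)
    profile = kwargs.get("profile")
    config = kwargs.get("config")
    results = []
    for mult in multipliers:
        if mult == 1.0:
            results.append(base)
        else:
            results.append(activated_cells(model, mosaic, electrode, mult * thr,
                                           pulse=pulse, profile=profile,
                                           config=config))
    return RecruitmentCurve(position=np.array([electrode.x, electrode.y]),
                            threshold=thr, multipliers=np.asarray(multipliers),
                            results=results)
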