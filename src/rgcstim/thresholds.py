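"""Spike detection, latency, binary-search thresholds and 2-D threshold maps.

Threshold is the minimum stimulus current that evokes a somatic action
potential (0 mV upward crossing) within a 40 ms run; latency is the time from
stimulus onset to the action-potential peak.  The search brackets the
threshold by amplitude doubling from an initial guess, then bisects to the
requested resolution (0.1 uA for the 10 um electrode, 0.5 uA otherwise).
Maps scan the electrode over an x-y grid at fixed height above the somatic
center; every grid position is searched independently, so serial and
multi-worker scans are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .cable import CableModel, FieldStimulus, SimulationConfig
from .field import ElectrodeSpec, InhomogeneityProfile, PulseSpec, transfer_resistance

__all__ = [
    "detect_spikes",
    "latency",
    "ThresholdResult",
    "find_threshold",
    "ScanGrid",
    "ThresholdMap",
    "threshold_map",
    "ais_threshold",
]

DEFAULT_CAP = 200.0      # uA, amplitude beyond which a position is not excitable
DEFAULT_START = 1.0      # uA, initial bracketing guess


def detect_spikes(t, v) -> np.ndarray:
    """Spike peak times: one event per contiguous run of Vm >= 0 mV.

    The event time is the local Vm maximum inside each suprathreshold run, so
    consecutive samples above 0 mV within one run merge into a single spike.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    above = v >= 0.0
    if not above.any():
        return np.empty(0)
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        ends = ends + [len(v)]
    peaks = []
    for s, e in zip(starts, ends):
        peaks.append(t[s + int(np.argmax(v[s:e]))])
    return np.asarray(peaks)


def latency(onset_ms: float, spikes) -> float:
    """First spike peak minus stimulus onset (ms); nan without a spike."""
    spikes = np.asarray(spikes, dtype=float)
    spikes = spikes[spikes >= onset_ms]
    if len(spikes) == 0:
        return float("nan")
    return float(spikes[0] - onset_ms)


@dataclass
class ThresholdResult:
    """Outcome of one binary search at one electrode position."""

    threshold: float          # uA; nan when not excitable below the cap
    latency: float            # ms at threshold; nan when not excitable
    excitable: bool
    initiation_comp: int = -1
    initiation_region: str = ""
    n_probes: int = 0
    monotone: bool = True

    def __float__(self) -> float:
        return self.threshold


def evoked_spikes(peaks, pulse: PulseSpec) -> np.ndarray:
    """Spike peaks attributable to the stimulus rather than the pulse artifact.

    Strong fields can polarize compartments under the electrode above 0 mV
    during the pulse itself without triggering a regenerative action
    potential, so an evoked somatic spike is required to peak after the
    biphasic pulse has ended.
    """
    peaks = np.asarray(peaks, dtype=float)
    t_end = pulse.onset_ms + 2.0 * pulse.phase_ms + pulse.gap_ms
    return peaks[peaks > t_end]


def _probe(model: CableModel, electrode: ElectrodeSpec, amplitude: float,
           pulse: PulseSpec, profile, config: SimulationConfig):
    from dataclasses import replace
    stim = FieldStimulus(electrode, replace(pulse, amplitude=amplitude), profile)
    trace = model.run(config, stimulus=stim)
    peaks = evoked_spikes(detect_spikes(trace.t, trace.soma), pulse)
    lat = latency(pulse.onset_ms, peaks)
    fc = trace.first_cross_ms
    init = -1
    if np.any(np.isfinite(fc)):
        init = int(np.nanargmin(fc))
    return len(peaks) > 0 and np.isfinite(lat), lat, init


def find_threshold(model: CableModel, electrode: ElectrodeSpec, *,
                   tolerance: float | None = None,
                   pulse: PulseSpec | None = None,
                   profile: InhomogeneityProfile | None = None,
                   config: SimulationConfig | None = None,
                   i_start: float = DEFAULT_START,
                   i_cap: float = DEFAULT_CAP) -> ThresholdResult:
    """Binary-search the threshold current at one electrode position.

    The returned amplitude spikes while (amplitude - tolerance) does not.
    Positions where even the cap amplitude fails to spike come back flagged
    not-excitable rather than raising.  The final bracket is re-checked so a
    non-monotone spike/amplitude relation would be detected and re-scanned
    linearly at tolerance resolution.
    """
    if tolerance is None:
        tolerance = 0.1 if electrode.radius <= 10.0 else 0.5
    pulse = pulse or PulseSpec(amplitude=1.0)
    config = config or SimulationConfig(duration=40.0)
    n_probes = 0

    def probe(amp):
        nonlocal n_probes
        n_probes += 1
        return _probe(model, electrode, amp, pulse, profile, config)

    hi = i_start
    spiked, lat, init = probe(hi)
    while not spiked:
        if hi >= i_cap:
            return ThresholdResult(float("nan"), float("nan"), False,
                                   n_probes=n_probes)
        hi = min(2.0 * hi, i_cap)
        spiked, lat, init = probe(hi)
    lo = 0.0 if hi == i_start else hi / 2.0

    hi_lat, hi_init = lat, init
    while hi - lo > tolerance:
        mid = 0.5 * (hi + lo)
        spiked, lat, init = probe(mid)
        if spiked:
            hi, hi_lat, hi_init = mid, lat, init
        else:
            lo = mid

    monotone = True
    if lo > 0.0:
        spiked_lo, _, _ = probe(lo)
        if spiked_lo:
            monotone = False
            # fall back to a linear scan at tolerance resolution
            amp = tolerance
            while amp <= i_cap:
                spiked, lat, init = probe(amp)
                if spiked:
                    hi, hi_lat, hi_init = amp, lat, init
                    break
                amp += tolerance

    region = (str(model.cell.region[hi_init]) if hi_init >= 0 else "")
    return ThresholdResult(hi, hi_lat, True, hi_init, region, n_probes, monotone)


@dataclass
class ScanGrid:
    """Rectangular x-y scan at fixed electrode height above the somatic plane."""

    x0: float
    x1: float
    y0: float
    y1: float
    step: float = 10.0
    z: float = 40.0

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("grid step must be positive")

    @property
    def xs(self) -> np.ndarray:
        n = int(round((self.x1 - self.x0) / self.step))
        return self.x0 + self.step * np.arange(n + 1)

    @property
    def ys(self) -> np.ndarray:
        n = int(round((self.y1 - self.y0) / self.step))
        return self.y0 + self.step * np.arange(n + 1)

    def positions(self) -> np.ndarray:
        """(n, 2) electrode centers, row-major over y then x."""
        xs, ys = self.xs, self.ys
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class ThresholdMap:
    """Per-position threshold current, latency and spike-initiation site."""

    grid: ScanGrid
    positions: np.ndarray
    threshold: np.ndarray       # uA, nan = not excitable
    latency: np.ndarray         # ms
    initiation_comp: np.ndarray
    initiation_region: np.ndarray
    electrode_radius: float

    def min_position(self) -> np.ndarray:
        """Grid position of the lowest threshold."""
        return self.positions[int(np.nanargmin(self.threshold))]

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "x_um": self.positions[:, 0], "y_um": self.positions[:, 1],
            "threshold_ua": self.threshold, "latency_ms": self.latency,
            "initiation_comp": self.initiation_comp,
            "initiation_region": self.initiation_region,
        })


def _map_one(model, pos, radius, z, kwargs):
    electrode = ElectrodeSpec(radius=radius, x=pos[0], y=pos[1], z=z)
    return find_threshold(model, electrode, **kwargs)


def threshold_map(model: CableModel, grid: ScanGrid, electrode_radius: float,
                  *, n_jobs: int = 1, **kwargs) -> ThresholdMap:
    """Independent binary search per grid position (parallel-map contract).

    Results do not depend on evaluation order or worker count; per-position
    not-excitable outcomes are aggregated, never raised.
    """
    positions = grid.positions()
    if n_jobs == 1:
        results = [_map_one(model, p, electrode_radius, grid.z, kwargs)
                   for p in positions]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_map_one)(model, p, electrode_radius, grid.z, kwargs)
            for p in positions)
    return ThresholdMap(
        grid=grid,
        positions=positions,
        threshold=np.array([r.threshold for r in results]),
        latency=np.array([r.latency for r in results]),
        initiation_comp=np.array([r.initiation_comp for r in results]),
        initiation_region=np.array([r.initiation_region for r in results],
                                   dtype=object),
        electrode_radius=electrode_radius,
    )


def ais_threshold(model: CableModel, electrode_radius: float = 10.0,
                  z: float = 40.0, **kwargs) -> float:
    """Mean threshold over the proximal end, midpoint and distal end of the AIS.

    Returns nan if any of the three sites is not excitable below the cap.
    """
    sites = model.cell.ais_sites()
    vals = []
    for comp in sites:
        x, y = model.cell.midpoint[comp][:2]
        electrode = ElectrodeSpec(radius=electrode_radius, x=x, y=y, z=z)
        res = find_threshold(model, electrode, **kwargs)
        if not res.excitable:
            return float("nan")
        vals.append(res.threshold)
    return float(np.mean(vals))
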