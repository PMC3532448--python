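"""Multi-compartment cable engine: assembly, implicit time stepping, recording.

:class:`CableModel` couples a segmented morphology with a membrane spec and
integrates the branched cable equation with a Crank-Nicolson voltage update,
staggered exact-exponential gate relaxation, and an O(N) tree (Hines) solve.
Extracellular stimulation enters through per-compartment potentials sampled at
compartment midpoints and applied as equivalent axial currents, so only
spatial differences of Ve drive the membrane.

Boundary conditions are sealed ends.  The rest state is obtained by a 200 ms
stimulus-free settling run before every protocol and cached per model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .channels import GATES, KINETICS, MembraneSpec, steady_states
from .field import (ElectrodeSpec, InhomogeneityProfile, PulseSpec,
                    pulse_current, transfer_vector)
from .morphology import SegmentedCell

__all__ = [
    "SimulationConfig",
    "SimulationTrace",
    "CurrentInjection",
    "FieldStimulus",
    "CableModel",
    "NumericalError",
    "isi_curve",
    "phase_portrait",
]


class NumericalError(RuntimeError):
    """Solver produced non-finite membrane potentials."""


@dataclass
class SimulationConfig:
    """Run settings: 0.025 ms steps, 40 ms stimulation windows by default."""

    dt: float = 0.025          # ms
    duration: float = 40.0     # ms
    temperature: float = 35.0  # degC, metadata
    record_sites: tuple = ()   # compartment indices; soma is always added
    snapshot_times: tuple = () # ms

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one step")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class CurrentInjection:
    """Rectangular intracellular current at one compartment (pA, ms)."""

    comp: int
    amplitude_pa: float
    onset_ms: float = 0.0
    duration_ms: float = 500.0


@dataclass
class FieldStimulus:
    """Extracellular stimulus: electrode + pulse (+ optional inhomogeneity)."""

    electrode: ElectrodeSpec
    pulse: PulseSpec
    profile: InhomogeneityProfile | None = None


@dataclass
class SimulationTrace:
    """Recorded membrane potentials and event annotations for one run."""

    t: np.ndarray                       # ms, uniform with step dt
    vm: np.ndarray                      # (n_sites, n_t) mV
    sites: np.ndarray                   # compartment indices of vm rows
    dt: float
    snapshots: dict = field(default_factory=dict)   # time ms -> (N,) Vm
    first_cross_ms: np.ndarray | None = None        # per compartment, nan if none
    meta: dict = field(default_factory=dict)

    def at(self, comp: int) -> np.ndarray:
        """Vm time series recorded at a compartment."""
        hits = np.flatnonzero(self.sites == comp)
        if len(hits) == 0:
            raise KeyError(f"compartment {comp} was not recorded")
        return self.vm[hits[0]]

    @property
    def soma(self) -> np.ndarray:
        return self.vm[0]


class CableModel:
    """Discretized RGC: axial network, capacitances and channel densities.

    Axial conductances follow from Ra and the cylinder geometry (series
    half-compartment resistances); capacitance and conductances scale with
    lateral membrane area.  The passive axial operator has zero row sums
    (Kirchhoff) and symmetric coupling.
    """

    def __init__(self, cell: SegmentedCell, spec: MembraneSpec | None = None):
        self.cell = cell
        self.spec = spec or MembraneSpec.default()
        n = cell.n_comp
        if np.any(cell.length <= 0) or np.any(cell.diameter <= 0):
            raise ValueError("zero-length or zero-diameter compartment")
        area_cm2 = cell.area * 1e-8
        self.area_cm2 = area_cm2
        self.c_nf = self.spec.cm * area_cm2 * 1e3
        self.parent = cell.parent.astype(np.int64)

        # axial conductance to parent in uS
        radius_cm = cell.diameter * 1e-4 / 2.0
        half_r = self.spec.ra * (cell.length * 1e-4 / 2.0) / (math.pi * radius_cm ** 2)
        g_ax = np.zeros(n)
        for i in range(1, n):
            g_ax[i] = 1e6 / (half_r[i] + half_r[self.parent[i]])
        self.g_ax = g_ax

        gbar = np.empty((n, 6))
        for i in range(n):
            c = self.spec.for_region(str(cell.region[i]))
            gbar[i] = (c.gna, c.gk, c.ga, c.gca, c.gkca, c.gl)
        self.gbar = gbar * area_cm2[:, None] * 1e3  # mS/cm^2 -> uS

        shell_um = np.minimum(KINETICS["ca_shell"], cell.diameter / 2.0)
        self.cafac = 1e-3 / (2.0 * _kernel_faraday() * shell_um * 1e-4)

        t_kelvin = KINETICS["temperature"] + 273.15
        nernst = 1e3 * 8.314462 * t_kelvin / (2.0 * 96485.332)
        self.consts = np.array([
            self.spec.ena, self.spec.ek, self.spec.el,
            KINETICS["kca_kd"], KINETICS["kca_hill"],
            KINETICS["ca_residual"], KINETICS["ca_external"],
            KINETICS["ca_tau"], nernst, KINETICS["rate_scale"],
            KINETICS["na_act_shift"],
        ])
        self._rest = None

    @property
    def n_comp(self) -> int:
        return self.cell.n_comp

    @property
    def soma_index(self) -> int:
        return self.cell.soma_index

    # -- state -------------------------------------------------------------
    def _initial_state(self, v0: float):
        n = self.n_comp
        v = np.full(n, v0)
        ss = steady_states(v0)
        gates = np.tile([ss[g][0] for g in GATES], (n, 1))
        ca = np.full(n, KINETICS["ca_residual"])
        return v, gates, ca

    def rest_state(self, settle_ms: float = 200.0, dt: float = 0.025):
        """Stimulus-free settling from EL; cached per model instance."""
        if self._rest is None:
            v, gates, ca = self._initial_state(self.spec.el)
            n_steps = int(round(settle_ms / dt))
            out = self._run_kernel(v, gates, ca, n_steps, dt,
                                   phi=np.zeros(self.n_comp),
                                   stim=np.zeros(n_steps + 1),
                                   injections=(),
                                   rec_idx=np.array([self.soma_index]),
                                   snap_steps=np.empty(0, dtype=np.int64),
                                   dense=False, diagnostics=False)
            _, _, _, v_end, gates_end, ca_end, _ = out
            self._rest = (v_end, gates_end, ca_end)
        return tuple(a.copy() for a in self._rest)

    @property
    def resting_potential(self) -> float:
        v, _, _ = self.rest_state()
        return float(v[self.soma_index])

    # -- integration -------------------------------------------------------
    def _run_kernel(self, v, gates, ca, n_steps, dt, phi, stim, injections,
                    rec_idx, snap_steps, dense, diagnostics):
        inj = list(injections)
        for i in inj:
            if not (0 <= i.comp < self.n_comp):
                raise ValueError(f"unknown injection site {i.comp}")
        inj_comp = np.array([i.comp for i in inj], dtype=np.int64)
        inj_na = np.array([i.amplitude_pa * 1e-3 for i in inj])
        inj_on = np.array([i.onset_ms for i in inj])
        inj_off = np.array([i.onset_ms + i.duration_ms for i in inj])
        if len(inj) == 0:
            inj_comp = np.empty(0, dtype=np.int64)
            inj_na = inj_on = inj_off = np.empty(0)
        return _kernel.simulate(
            self.parent, self.g_ax, self.c_nf, self.gbar, self.area_cm2,
            self.cafac, self.consts, v, gates, ca, n_steps, dt,
            phi, stim, inj_comp, inj_na, inj_on, inj_off,
            rec_idx, snap_steps, dense, diagnostics)

    def run(self, config: SimulationConfig | None = None,
            stimulus: FieldStimulus | None = None,
            injections=(), initial=None, *, settle: bool = True,
            phi: np.ndarray | None = None, stim_waveform=None,
            dense: bool = False, diagnostics: bool = False) -> SimulationTrace:
        """Integrate one protocol and return the recorded trace.

        ``stimulus`` builds the per-compartment field from an electrode and
        pulse; alternatively a raw transfer vector ``phi`` (mV/uA) plus a
        stimulus current waveform callable/array can be supplied.  The run
        starts from the cached rest state unless ``initial`` overrides it.
        """
        config = config or SimulationConfig()
        n_steps = config.n_steps
        t = np.arange(n_steps + 1) * config.dt

        if stimulus is not None:
            phi_vec = transfer_vector(self.cell.midpoint, stimulus.electrode,
                                      stimulus.profile)
            stim = pulse_current(stimulus.pulse, t)
        elif phi is not None:
            phi_vec = np.asarray(phi, dtype=float)
            if callable(stim_waveform):
                stim = np.array([stim_waveform(tk) for tk in t])
            elif stim_waveform is not None:
                stim = np.asarray(stim_waveform, dtype=float)
            else:
                stim = np.zeros(n_steps + 1)
        else:
            phi_vec = np.zeros(self.n_comp)
            stim = np.zeros(n_steps + 1)

        if initial is not None:
            v, gates, ca = (a.copy() for a in initial)
        elif settle:
            v, gates, ca = self.rest_state(dt=min(config.dt, 0.025))
        else:
            v, gates, ca = self._initial_state(self.spec.el)

        rec = [self.soma_index] + [s for s in config.record_sites
                                   if s != self.soma_index]
        rec_idx = np.asarray(rec, dtype=np.int64)
        snap_steps = np.unique(np.round(np.asarray(config.snapshot_times, float)
                                        / config.dt).astype(np.int64))

        out = self._run_kernel(v, gates, ca, n_steps, config.dt, phi_vec, stim,
                               injections, rec_idx, snap_steps, dense, diagnostics)
        v_rec, snaps, first_cross, v_end, _, _, resid = out
        if not np.all(np.isfinite(v_rec)):
            raise NumericalError(
                f"non-finite membrane potential (max |Vm| at step "
                f"{int(np.argmax(~np.isfinite(v_rec.max(axis=0))))})")

        fc_ms = np.where(first_cross >= 0, first_cross * config.dt, np.nan)
        snapshots = {float(s * config.dt): snaps[k]
                     for k, s in enumerate(snap_steps)}
        meta = {"temperature": config.temperature, "dt": config.dt,
                "max_residual": float(resid)}
        if stimulus is not None:
            meta["electrode"] = stimulus.electrode
            meta["pulse"] = stimulus.pulse
        return SimulationTrace(t=t, vm=v_rec, sites=rec_idx, dt=config.dt,
                               snapshots=snapshots, first_cross_ms=fc_ms,
                               meta=meta)


def _kernel_faraday() -> float:
    return 96485.332


# ---------------------------------------------------------------------------
# Trace analyses (calibration protocols)
# ---------------------------------------------------------------------------

def isi_curve(trace: SimulationTrace, site: int | None = None) -> float:
    """Mean inter-spike interval (ms) from spike peaks; nan if < 2 spikes."""
    from .thresholds import detect_spikes
    v = trace.soma if site is None else trace.at(site)
    peaks = detect_spikes(trace.t, v)
    if len(peaks) < 2:
        return float("nan")
    return float(np.mean(np.diff(peaks)))


def phase_portrait(trace: SimulationTrace, site: int | None = None):
    """(Vm, dVm/dt) pairs using centered finite differences."""
    v = trace.soma if site is None else trace.at(site)
    dv = np.gradient(v, trace.dt)
    return v, dv
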