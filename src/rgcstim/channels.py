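"""Membrane biophysics: five-channel RGC gating kinetics and conductance tables.

The excitability formalism is the classic retinal-ganglion-cell five-channel
Hodgkin-Huxley set: transient Na (m^3 h), delayed-rectifier K (n^4), A-type
K (a^3 h_A), L-type Ca (c^3) and Ca-gated K, plus an ohmic leak.  Rate
functions and the calcium-pool constants live in one editable kinetics table
(:data:`KINETICS`) so alternate parameterizations can be swapped in.  The
calcium reversal is not fixed: it follows the intracellular pool through the
Nernst relation.

Conductance densities are region specific (mS/cm^2); the AIS carries a ten-fold
sodium density relative to the soma, which is what makes it the spike
initiation zone under extracellular stimulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KINETICS",
    "GATES",
    "RegionConductances",
    "MembraneSpec",
    "ChannelState",
    "rate_functions",
    "steady_states",
    "gate_step",
    "ionic_current",
    "calcium_step",
    "nernst_eca",
]

#: Kinetics table: calcium pool and misc constants (adopted values from the
#: published RGC formalism; flagged as tunable, units in comments).
KINETICS = {
    "ca_residual": 1e-4,   # mM, resting intracellular calcium floor
    "ca_external": 1.8,    # mM
    "ca_tau": 1.5,         # ms, calcium removal time constant
    "ca_shell": 0.1,       # um, submembrane shell depth receiving Ca influx
    "kca_kd": 1e-3,        # mM, half-activation of the Ca-gated K channel
    "kca_hill": 2.0,       # Hill exponent of K(Ca) activation
    "temperature": 35.0,   # degC, metadata; kinetics applied as published
    "rate_scale": 1.0,     # optional uniform scaling of all rate functions
    # Depolarizing shift (mV) of the Na activation curve.  The published
    # room-temperature rate table leaves a standing Na window current at the
    # -62.5 mV leak reversal, which turns the high-gNa AIS into a pacemaker;
    # the study's cells are silent at rest, so the activation midpoint is
    # calibrated (once) to close the window at rest while leaving spike
    # generation and availability intact.
    "na_act_shift": 2.0,
}

GATES = ("m", "h", "n", "a", "ha", "c")

FARADAY = 96485.332  # C/mol
GAS_R = 8.314462     # J/(mol K)


def _exprel(u):
    """u / (exp(u) - 1) with the removable singularity at u = 0 filled in."""
    u = np.asarray(u, dtype=float)
    out = np.where(np.abs(u) < 1e-9, 1.0 - 0.5 * u,
                   u / np.expm1(np.where(np.abs(u) < 1e-9, 1.0, u)))
    return out if out.ndim else float(out)


def rate_functions(v):
    """Forward/backward rates (1/ms) for every gate at membrane voltage v (mV).

    All rates are finite and non-negative for finite v, including at the
    removable singularities of the (V - V0)/(exp - 1) forms.
    """
    v = np.asarray(v, dtype=float)
    s = KINETICS["rate_scale"]
    vm = v - KINETICS["na_act_shift"]
    rates = {
        "m": (6.0 * _exprel(-0.1 * (vm + 30.0)), 20.0 * np.exp(-(vm + 55.0) / 18.0)),
        "h": (0.4 * np.exp(-(v + 50.0) / 20.0), 6.0 / (1.0 + np.exp(-0.1 * (v + 20.0)))),
        "n": (0.2 * _exprel(-0.1 * (v + 40.0)), 0.4 * np.exp(-(v + 50.0) / 80.0)),
        "a": (0.06 * _exprel(-0.1 * (v + 90.0)), 0.1 * np.exp(-(v + 30.0) / 10.0)),
        "ha": (0.04 * np.exp(-(v + 70.0) / 20.0), 0.6 / (1.0 + np.exp(-0.1 * (v + 40.0)))),
        "c": (3.0 * _exprel(-0.1 * (v + 13.0)), 10.0 * np.exp(-(v + 38.0) / 18.0)),
    }
    if s != 1.0:
        rates = {g: (s * a, s * b) for g, (a, b) in rates.items()}
    return rates


def steady_states(v):
    """Per-gate (x_inf, tau_ms) at clamped voltage v."""
    out = {}
    for g, (a, b) in rate_functions(v).items():
        out[g] = (a / (a + b), 1.0 / (a + b))
    return out


@dataclass
class ChannelState:
    """Gating variables and intracellular calcium for one compartment."""

    m: float
    h: float
    n: float
    a: float
    ha: float
    c: float
    ca: float = KINETICS["ca_residual"]

    @classmethod
    def at_rest(cls, v: float) -> "ChannelState":
        ss = steady_states(v)
        return cls(*(ss[g][0] for g in GATES), ca=KINETICS["ca_residual"])

    def gates(self) -> dict:
        return {g: getattr(self, g) for g in GATES}


def gate_step(state: ChannelState, v: float, dt: float) -> ChannelState:
    """Advance every gate by exact exponential relaxation over dt (ms).

    For clamped voltage the first-order gate ODE has the closed-form solution
    x(t+dt) = x_inf + (x - x_inf) exp(-dt/tau); the update is therefore exact
    and two half steps compose to one full step to rounding error.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ss = steady_states(v)
    new = {}
    for g in GATES:
        inf, tau = ss[g]
        x = getattr(state, g)
        new[g] = inf + (x - inf) * math.exp(-dt / tau)
    return replace(state, **new)


def nernst_eca(ca: float, ca_external: float | None = None,
               temperature: float | None = None) -> float:
    """Calcium reversal potential (mV) from the intracellular pool."""
    ca_o = KINETICS["ca_external"] if ca_external is None else ca_external
    temp = KINETICS["temperature"] if temperature is None else temperature
    t_kelvin = temp + 273.15
    fac = 1e3 * GAS_R * t_kelvin / (2.0 * FARADAY)  # mV
    return fac * math.log(ca_o / ca)


def kca_activation(ca: float) -> float:
    """Saturating Hill activation of the Ca-gated K conductance."""
    x = (ca / KINETICS["kca_kd"]) ** KINETICS["kca_hill"]
    return x / (1.0 + x)


@dataclass(frozen=True)
class RegionConductances:
    """Maximal conductance densities for one region, mS/cm^2."""

    gna: float
    gk: float
    ga: float
    gca: float
    gkca: float
    gl: float = 0.005

    def __post_init__(self):
        for name in ("gna", "gk", "ga", "gca", "gkca", "gl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class MembraneSpec:
    """Region-resolved membrane parameters.

    Defaults are the study conditions: dendrites gNa=40, gK=12, gA=36, gCa=2,
    gKCa=0.05; soma and hillock gNa=70, gK=18, gA=54, gCa=1.5, gKCa=0.065;
    AIS as soma but gNa=700; axon proper gNa=70, gK=18, gKCa=0.065 with no A
    or Ca current; gL=0.005 everywhere.  ENa=35, EK=-75, EL=-62.5 mV;
    Cm=1 uF/cm^2; Ra=110 Ohm cm.
    """

    regions: dict = field(default_factory=dict)
    ena: float = 35.0
    ek: float = -75.0
    el: float = -62.5
    cm: float = 1.0     # uF/cm^2
    ra: float = 110.0   # Ohm cm

    @classmethod
    def default(cls) -> "MembraneSpec":
        soma = RegionConductances(gna=70, gk=18, ga=54, gca=1.5, gkca=0.065)
        return cls(regions={
            "dendrite": RegionConductances(gna=40, gk=12, ga=36, gca=2, gkca=0.05),
            "soma": soma,
            "hillock": soma,
            "ais": replace(soma, gna=700.0),
            "axon": RegionConductances(gna=70, gk=18, ga=0, gca=0, gkca=0.065),
        })

    def for_region(self, region: str) -> RegionConductances:
        return self.regions[region]

    def with_dendritic_gna(self, gna: float) -> "MembraneSpec":
        """Pure table override of dendritic sodium density (40-80 sweep)."""
        regions = dict(self.regions)
        regions["dendrite"] = replace(regions["dendrite"], gna=gna)
        return replace(self, regions=regions)

    def passive(self) -> "MembraneSpec":
        """All active conductances zeroed; leak only (for cable validation)."""
        regions = {r: RegionConductances(0, 0, 0, 0, 0, gl=c.gl)
                   for r, c in self.regions.items()}
        return replace(self, regions=regions)

    def to_dict(self) -> dict:
        return {
            "reversals_mV": {"ena": self.ena, "ek": self.ek, "el": self.el},
            "cm_uF_per_cm2": self.cm,
            "ra_ohm_cm": self.ra,
            "conductances_mS_per_cm2": {
                r: {k: getattr(c, k) for k in ("gna", "gk", "ga", "gca", "gkca", "gl")}
                for r, c in self.regions.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MembraneSpec":
        rev = d.get("reversals_mV", {})
        regions = {r: RegionConductances(**v)
                   for r, v in d["conductances_mS_per_cm2"].items()}
        return cls(regions=regions,
                   ena=rev.get("ena", 35.0), ek=rev.get("ek", -75.0),
                   el=rev.get("el", -62.5),
                   cm=d.get("cm_uF_per_cm2", 1.0), ra=d.get("ra_ohm_cm", 110.0))


def ionic_current(v: float, state: ChannelState, cond: RegionConductances,
                  spec: MembraneSpec | None = None):
    """Total membrane current density (uA/cm^2) and per-channel breakdown.

    Outward current is positive.  The calcium reversal is computed from the
    compartment's calcium pool via the Nernst relation.
    """
    spec = spec or MembraneSpec.default()
    eca = nernst_eca(state.ca)
    parts = {
        "na": cond.gna * state.m ** 3 * state.h * (v - spec.ena),
        "k": cond.gk * state.n ** 4 * (v - spec.ek),
        "a": cond.ga * state.a ** 3 * state.ha * (v - spec.ek),
        "ca": cond.gca * state.c ** 3 * (v - eca),
        "kca": cond.gkca * kca_activation(state.ca) * (v - spec.ek),
        "leak": cond.gl * (v - spec.el),
    }
    return sum(parts.values()), parts


def calcium_step(ca: float, ica: float, dt: float, *, diameter: float | None = None,
                 shell: float | None = None) -> float:
    """Advance the calcium pool by the exact solution of its linear ODE.

    Inward calcium current (``ica`` < 0, uA/cm^2) feeds a submembrane shell of
    depth ``shell`` um via the Faraday constant; the pool relaxes toward the
    residual concentration with the table's time constant and never falls
    below it.  ``diameter`` caps the shell at the compartment radius.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    shell_um = KINETICS["ca_shell"] if shell is None else shell
    if diameter is not None:
        shell_um = min(shell_um, diameter / 2.0)
    shell_cm = shell_um * 1e-4
    tau = KINETICS["ca_tau"]
    res = KINETICS["ca_residual"]
    # uA/cm^2 -> mM/ms source in the shell
    source = -ica * 1e-3 / (2.0 * FARADAY * shell_cm)
    target = res + source * tau
    new = target + (ca - target) * math.exp(-dt / tau)
    return max(new, res)
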