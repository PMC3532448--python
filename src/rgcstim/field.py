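"""Extracellular disk-electrode field, transfer resistance, pulse waveform.

The electrode is a monopolar, purely resistive disk of radius ``a`` in an
isotropic ohmic medium.  The potential at radial distance r and axial distance
z from the disk center is the standard oblate-spheroidal (Newman) solution,

    V(r, z) = (2/pi) * I * Rs * arcsin( 2a / (sqrt((r-a)^2+z^2) + sqrt((r+a)^2+z^2)) ),

normalized so that V = I*Rs at the disk surface center.  ``Rs`` is the
calibrated electrode transfer resistance; with stimulus currents expressed in
uA the calibrated value (0.725 for a 10 um radius electrode 40 um above the
cell) converts uA to volts of surface potential, and this module returns
potentials in mV.  Transfer resistance for other electrode sizes follows
surface-area scaling, Rs(a) = Rs0 * (a0/a)^2.

Depth-dependent tissue inhomogeneity multiplies Rs by an axial scaling
coefficient C(z) that peaks (C=1) at the somatic layer z=0 and decays to
R_distant/R_peak far from it.

The stimulus is a charge-balanced cathodic-first biphasic pulse, 0.1 ms per
phase, no inter-phase gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectrodeSpec",
    "PulseSpec",
    "InhomogeneityProfile",
    "disk_potential",
    "transfer_resistance",
    "inhomogeneity_coeff",
    "pulse_current",
    "field_at_compartments",
    "transfer_vector",
]

#: calibration reference: 10 um radius platinum disk, 40 um above the cell
REFERENCE_RADIUS = 10.0
REFERENCE_RS = 0.725


def transfer_resistance(radius: float, a0: float = REFERENCE_RADIUS,
                        rs0: float = REFERENCE_RS) -> float:
    """Electrode transfer resistance by surface-area scaling from (a0, Rs0)."""
    if radius <= 0:
        raise ValueError("electrode radius must be positive")
    return rs0 * (a0 / radius) ** 2


@dataclass
class ElectrodeSpec:
    """Disk electrode geometry and calibrated transfer resistance.

    ``z`` is the axial height of the disk plane above the somatic plane (um);
    the disk is parallel to the retina with its axis along z.
    """

    radius: float
    x: float = 0.0
    y: float = 0.0
    z: float = 40.0
    rs: float | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("electrode radius must be positive")
        if self.rs is None:
            self.rs = transfer_resistance(self.radius)
        if self.rs <= 0:
            raise ValueError("transfer resistance must be positive")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class PulseSpec:
    """Charge-balanced cathodic-first biphasic pulse.

    ``amplitude`` is the phase current magnitude in uA; cathodic current is
    signed negative, so the first phase delivers -amplitude.
    """

    amplitude: float
    phase_ms: float = 0.1
    gap_ms: float = 0.0
    onset_ms: float = 1.0

    def __post_init__(self):
        if self.phase_ms <= 0:
            raise ValueError("phase duration must be positive")
        if self.gap_ms < 0:
            raise ValueError("inter-phase gap must be non-negative")


def pulse_current(pulse: PulseSpec, t) -> np.ndarray:
    """Signed stimulus current (uA) at time t (ms): -I then +I, zero outside."""
    t = np.asarray(t, dtype=float)
    rel = t - pulse.onset_ms
    ph, gap = pulse.phase_ms, pulse.gap_ms
    out = np.zeros_like(rel)
    out = np.where((rel >= 0) & (rel < ph), -pulse.amplitude, out)
    out = np.where((rel >= ph + gap) & (rel < 2 * ph + gap), pulse.amplitude, out)
    return out if out.ndim else float(out)


@dataclass
class InhomogeneityProfile:
    """Depth profile of tissue resistivity perpendicular to the electrode.

    ``ratio`` = R_peak/R_distant >= 1; resistivity peaks at the somatic layer
    (z = 0) and decays as a Gaussian bump of scale ``width`` um, so that
    C(0) = 1 (peak resistivity equals Rs) and C -> 1/ratio far from the layer.
    ratio = 1 recovers homogeneous tissue.
    """

    ratio: float = 1.0
    width: float = 20.0

    def __post_init__(self):
        if self.ratio < 1.0:
            raise ValueError("R_peak/R_distant ratio must be >= 1")
        if self.width <= 0:
            raise ValueError("width must be positive")


def inhomogeneity_coeff(z, profile: InhomogeneityProfile) -> np.ndarray:
    """Axial scaling coefficient C(z): even in z, maximal (1) at z = 0."""
    z = np.asarray(z, dtype=float)
    lo = 1.0 / profile.ratio
    out = lo + (1.0 - lo) * np.exp(-((z / profile.width) ** 2))
    return out if out.ndim else float(out)


def disk_potential(i_ua: float, electrode: ElectrodeSpec, points) -> np.ndarray:
    """Extracellular potential (mV) of the disk at one or more 3-D points (um).

    Rotationally symmetric about the electrode axis, continuous everywhere off
    the disk, and equal to I*Rs (in volts, i.e. 1e3*I*Rs mV) at the disk
    surface center.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = pts - electrode.center
    r = np.hypot(d[:, 0], d[:, 1])
    z = d[:, 2]
    a = electrode.radius
    denom = np.sqrt((r - a) ** 2 + z ** 2) + np.sqrt((r + a) ** 2 + z ** 2)
    arg = np.clip(2.0 * a / denom, -1.0, 1.0)
    v = (2.0 / np.pi) * i_ua * electrode.rs * 1e3 * np.arcsin(arg)
    return v if np.asarray(points).ndim > 1 else float(v[0])


def transfer_vector(midpoints, electrode: ElectrodeSpec,
                    profile: InhomogeneityProfile | None = None) -> np.ndarray:
    """Per-compartment potential (mV) per unit stimulus current (1 uA).

    Composes the disk solution with the depth-dependent resistivity scaling
    C(z) evaluated at each compartment midpoint.  The actual extracellular
    potential at time t is ``transfer_vector * pulse_current(t)``.
    """
    mid = np.atleast_2d(np.asarray(midpoints, dtype=float))
    phi = disk_potential(1.0, electrode, mid)
    if profile is not None and profile.ratio != 1.0:
        phi = phi * inhomogeneity_coeff(mid[:, 2], profile)
    return phi


def field_at_compartments(midpoints, electrode: ElectrodeSpec, pulse: PulseSpec,
                          t, profile: InhomogeneityProfile | None = None) -> np.ndarray:
    """Extracellular potential (mV) at each compartment midpoint at time t."""
    phi = transfer_vector(midpoints, electrode, profile)
    return phi * pulse_current(pulse, t)
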