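"""Cable engine: assembly, implicit integration, analytic benchmarks."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.linalg import expm

from rgcstim import (CableModel, CurrentInjection, ElectrodeSpec,
                     FieldStimulus, Morphology, PulseSpec, Section,
                     SimulationConfig, isi_curve, phase_portrait,
                     segmentize, soma_cylinder)
from rgcstim.cable import SimulationTrace
from rgcstim.thresholds import detect_spikes

EL = -62.5


def straight_cable(length=500.0, diameter=2.0, max_len=4.0):
    soma = soma_cylinder(2.0)
    sec = Section(1, "axon", 0, soma.p1, soma.p1 + np.array([length, 0.0, 0.0]),
                  diameter)
    return segmentize(Morphology([soma, sec]), max_len=max_len)


class TestAssembly:
    def test_identical_compartments_couple_symmetrically(self, passive_spec):
        cell = straight_cable(length=20.0, diameter=2.0, max_len=10.0)
        model = CableModel(cell, passive_spec)
        axon = np.flatnonzero(cell.sec_id == 1)
        # conductance between equal cylinders: g = pi a^2 / (Ra L)
        a_cm, l_cm = 1e-4, 10e-4
        expected = math.pi * a_cm ** 2 / (model.spec.ra * l_cm) * 1e6
        assert model.g_ax[axon[1]] == pytest.approx(expected, rel=1e-12)

    def test_doubling_ra_halves_axial_conductances(self, passive_spec):
        cell = straight_cable()
        g1 = CableModel(cell, passive_spec).g_ax
        g2 = CableModel(cell, replace(passive_spec, ra=220.0)).g_ax
        np.testing.assert_allclose(g2[1:], g1[1:] / 2.0, rtol=1e-12)

    def test_passive_axial_operator_conserves_current(self, passive_spec):
        # Kirchhoff: the axial operator's rows sum to zero
        cell = straight_cable(length=60.0, max_len=10.0)
        model = CableModel(cell, passive_spec)
        n = model.n_comp
        L = np.zeros((n, n))
        for i in range(1, n):
            p = model.parent[i]
            L[i, p] += model.g_ax[i]
            L[i, i] -= model.g_ax[i]
            L[p, i] += model.g_ax[i]
            L[p, p] -= model.g_ax[i]
        np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(L, L.T, atol=1e-12)

    def test_zero_geometry_rejected(self, passive_spec):
        cell = straight_cable()
        cell.length[3] = 0.0
        with pytest.raises(ValueError):
            CableModel(cell, passive_spec)


class TestAgainstClosedForms:
    def test_two_compartment_system_matches_matrix_exponential(self, passive_spec):
        soma = soma_cylinder(10.0)
        sec = Section(1, "axon", 0, soma.p1, soma.p1 + np.array([10.0, 0, 0]), 2.0)
        cell = segmentize(Morphology([soma, sec]), max_len=12.0)
        model = CableModel(cell, passive_spec)
        n = model.n_comp
        assert n == 2
        A = np.zeros((n, n))
        for i in range(1, n):
            p = model.parent[i]
            A[i, p] += model.g_ax[i]; A[i, i] -= model.g_ax[i]
            A[p, i] += model.g_ax[i]; A[p, p] -= model.g_ax[i]
        A -= np.diag(model.gbar[:, 5])
        b = model.gbar[:, 5] * EL
        b[n - 1] += 50e-3  # 50 pA
        A = A / model.c_nf[:, None]
        b = b / model.c_nf
        vss = -np.linalg.solve(A, b)
        va = vss + expm(A * 0.5) @ (np.full(n, EL) - vss)

        inj = CurrentInjection(n - 1, 50.0, onset_ms=0.0, duration_ms=10.0)
        tr = model.run(SimulationConfig(duration=0.5, dt=2.5e-4,
                                        record_sites=tuple(range(n))),
                       injections=[inj], settle=False)
        vend = np.array([tr.at(i)[-1] for i in range(n)])
        np.testing.assert_allclose(vend, va, rtol=1e-8)

    def test_steady_state_matches_finite_cable_cosh_profile(self, passive_spec):
        # sealed cable, current injected at the far end; >10 compartments
        # per length constant
        cell = straight_cable(length=500.0, diameter=2.0, max_len=4.0)
        model = CableModel(cell, passive_spec)
        end = model.n_comp - 1
        inj = CurrentInjection(end, 100.0, onset_ms=0.0, duration_ms=1000.0)
        tr = model.run(SimulationConfig(duration=100.0,
                                        record_sites=tuple(range(model.n_comp))),
                       injections=[inj], settle=False)
        gl = 0.5  # mS/cm^2 in the passive fixture
        a_cm = 1e-4
        rm = 1.0 / (gl * 1e-3)                       # Ohm cm^2
        lam = math.sqrt(rm * a_cm / (2.0 * model.spec.ra))  # cm
        assert (lam * 1e4) / 4.0 > 10.0              # compartments per lambda
        r_a = model.spec.ra / (math.pi * a_cm ** 2)  # Ohm/cm
        L = 500e-4
        idx = np.flatnonzero(cell.sec_id == 1)
        xs = np.abs(cell.midpoint[idx, 0] - cell.midpoint[end, 0]) * 1e-4
        analytic = 1e-10 * r_a * lam * np.cosh((L - xs) / lam) / math.sinh(L / lam) * 1e3
        sim = np.array([tr.at(i)[-1] for i in idx]) - EL
        assert (np.abs(sim - analytic) / np.abs(analytic)).max() < 0.01

    def test_sealed_compartment_injection_reaches_ir_drop(self, passive_spec):
        cell = segmentize(Morphology([soma_cylinder(20.0)]), max_len=25.0)
        model = CableModel(cell, passive_spec)
        inj = CurrentInjection(0, 50.0, onset_ms=0.0, duration_ms=500.0)
        tr = model.run(SimulationConfig(duration=60.0), injections=[inj],
                       settle=False)
        g_us = 0.5 * (math.pi * 20.0 ** 2 * 1e-8) * 1e3
        assert tr.soma[-1] - EL == pytest.approx(50e-3 / g_us, rel=1e-9)


class TestExtracellularCoupling:
    def test_uniform_field_produces_no_response(self, model):
        wave = np.zeros(1601)
        wave[40:44] = -50.0
        wave[44:48] = 50.0
        quiet = model.run(SimulationConfig(duration=40.0))
        driven = model.run(SimulationConfig(duration=40.0),
                           phi=np.ones(model.n_comp), stim_waveform=wave)
        assert np.abs(driven.vm - quiet.vm).max() < 1e-9

    def test_tree_solver_equals_dense_solve(self, small_cell):
        model = CableModel(small_cell)
        assert model.n_comp <= 200
        stim = FieldStimulus(ElectrodeSpec(radius=10.0, x=30.0, y=0.0),
                             PulseSpec(amplitude=2.0))
        cfg = SimulationConfig(duration=5.0)
        tree = model.run(cfg, stimulus=stim)
        dense = model.run(cfg, stimulus=stim, dense=True)
        assert np.abs(tree.vm - dense.vm).max() < 1e-10

    def test_charge_is_conserved_each_step(self, passive_spec):
        # solve one Crank-Nicolson step with the tree solver, then evaluate
        # the per-compartment current balance in extended precision
        cell = straight_cable(length=100.0, diameter=2.0, max_len=5.0)
        model = CableModel(cell, passive_spec)
        n = model.n_comp
        dt = 0.025
        inj_na = 0.05
        tr = model.run(SimulationConfig(duration=dt, dt=dt,
                                        record_sites=tuple(range(n))),
                       injections=[CurrentInjection(n - 1, 50.0, 0.0, 1.0)],
                       settle=False)
        v0 = np.full(n, EL, dtype=np.longdouble)
        v1 = np.array([tr.at(i)[-1] for i in range(n)], dtype=np.longdouble)
        c = model.c_nf.astype(np.longdouble)
        gl = model.gbar[:, 5].astype(np.longdouble)
        gax = model.g_ax.astype(np.longdouble)
        resid = c * (v1 - v0) / np.longdouble(dt) \
            + 0.5 * gl * (v1 + v0) - gl * np.longdouble(EL)
        resid[n - 1] -= np.longdouble(inj_na)
        terms = [np.abs(c * (v1 - v0) / np.longdouble(dt)),
                 np.abs(0.5 * gl * (v1 + v0) - gl * np.longdouble(EL))]
        for i in range(1, n):
            p = model.parent[i]
            ax = 0.5 * gax[i] * ((v1[p] - v1[i]) + (v0[p] - v0[i]))
            resid[i] -= ax
            resid[p] += ax
            terms.append(np.abs(ax))
        biggest = max(float(t.max()) for t in terms)
        assert float(np.abs(resid).max()) < 1e-9 * biggest


class TestRunProtocols:
    def test_rest_is_near_leak_reversal_and_stable(self, model):
        assert abs(model.resting_potential - EL) < 3.0
        tr = model.run(SimulationConfig(duration=40.0))
        assert np.abs(tr.soma - tr.soma[0]).max() < 1.0

    def test_identical_runs_are_bitwise_identical(self, model):
        stim = FieldStimulus(ElectrodeSpec(radius=10.0, x=45.0, y=0.0),
                             PulseSpec(amplitude=1.5))
        a = model.run(SimulationConfig(duration=10.0), stimulus=stim)
        b = model.run(SimulationConfig(duration=10.0), stimulus=stim)
        np.testing.assert_array_equal(a.vm, b.vm)

    def test_sustained_injection_fires_repetitively(self, model):
        inj = CurrentInjection(model.soma_index, 40.0, onset_ms=10.0,
                               duration_ms=500.0)
        tr = model.run(SimulationConfig(duration=520.0), injections=[inj])
        assert len(detect_spikes(tr.t, tr.soma)) >= 2

    def test_zero_injection_is_no_injection(self, model):
        inj = CurrentInjection(model.soma_index, 0.0, onset_ms=1.0,
                               duration_ms=20.0)
        a = model.run(SimulationConfig(duration=30.0), injections=[inj])
        b = model.run(SimulationConfig(duration=30.0))
        np.testing.assert_array_equal(a.vm, b.vm)

    def test_injected_currents_sum_linearly(self, model):
        cfg = SimulationConfig(duration=30.0)
        two = [CurrentInjection(model.soma_index, 20.0, 1.0, 20.0),
               CurrentInjection(model.soma_index, 20.0, 1.0, 20.0)]
        one = [CurrentInjection(model.soma_index, 40.0, 1.0, 20.0)]
        a = model.run(cfg, injections=two)
        b = model.run(cfg, injections=one)
        np.testing.assert_allclose(a.vm, b.vm, atol=1e-12)

    def test_unknown_injection_site_rejected(self, model):
        with pytest.raises(ValueError):
            model.run(SimulationConfig(duration=1.0),
                      injections=[CurrentInjection(10 ** 6, 10.0, 0.0, 1.0)])

    def test_snapshots_capture_whole_cell(self, model):
        stim = FieldStimulus(ElectrodeSpec(radius=10.0, x=45.0, y=0.0),
                             PulseSpec(amplitude=2.0))
        tr = model.run(SimulationConfig(duration=5.0, snapshot_times=(1.5, 3.0)),
                       stimulus=stim)
        assert set(tr.snapshots) == {1.5, 3.0}
        for snap in tr.snapshots.values():
            assert snap.shape == (model.n_comp,)
            assert np.isfinite(snap).all()


class TestTraceAnalyses:
    def test_isi_of_equally_spaced_peaks(self):
        t = np.arange(0, 40.0, 0.025)
        v = np.full_like(t, -60.0)
        for peak in (10.0, 20.0, 30.0):
            v += 80.0 * np.exp(-((t - peak) / 0.2) ** 2)
        trace = SimulationTrace(t=t, vm=v[None, :], sites=np.array([0]), dt=0.025)
        assert isi_curve(trace) == pytest.approx(10.0, abs=0.05)

    def test_fewer_than_two_spikes_is_flagged_nan(self):
        t = np.arange(0, 10.0, 0.025)
        trace = SimulationTrace(t=t, vm=np.full((1, len(t)), -60.0),
                                sites=np.array([0]), dt=0.025)
        assert math.isnan(isi_curve(trace))

    def test_phase_portrait_of_sine_is_an_ellipse(self):
        dt = 0.01
        t = np.arange(0, 20.0, dt)
        w = 2.0 * math.pi / 5.0
        v = 30.0 * np.sin(w * t) - 40.0
        trace = SimulationTrace(t=t, vm=v[None, :], sites=np.array([0]), dt=dt)
        vv, dv = phase_portrait(trace)
        # (v - c)^2/A^2 + (dv/dt)^2/(Aw)^2 == 1 along the whole orbit
        r = ((vv + 40.0) / 30.0) ** 2 + (dv / (30.0 * w)) ** 2
        assert np.abs(r[2:-2] - 1.0).max() < 1e-3

    def test_isi_shrinks_with_injection_strength(self, model):
        isis = []
        for amp in (20.0, 40.0, 60.0):
            inj = CurrentInjection(model.soma_index, amp, 10.0, 500.0)
            tr = model.run(SimulationConfig(duration=520.0), injections=[inj])
            isis.append(isi_curve(tr))
        assert isis[0] > isis[1] > isis[2]


class TestTemporalConvergence:
    def test_halving_dt_leaves_threshold_unchanged(self, model):
        """0.025 -> 0.0125 ms steps move the AIS threshold by under 2%."""
        from rgcstim import ElectrodeSpec, find_threshold
        e = ElectrodeSpec(radius=10.0, x=58.0, y=0.0)
        base = find_threshold(model, e, tolerance=0.01).threshold
        fine = find_threshold(model, e, tolerance=0.01,
                              config=SimulationConfig(duration=40.0,
                                                      dt=0.0125)).threshold
        assert abs(fine - base) / base < 0.02
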