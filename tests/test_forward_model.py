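"""Passive cable dynamics and volume-conductor forward models."""

import dataclasses

import numpy as np
import pytest

from popkernel import forward_model as fm

DT = 2.0 ** -4


@pytest.fixture(scope="module")
def soma_only():
    return fm.Morphology(start=[[0, 0, 0]], end=[[0, 0, 20]], diam=[20.0],
                         parent=[-1], labels=["soma"])


class TestMorphology:
    def test_deterministic_given_seed(self):
        a = fm.build_stylized_l5(seed=42)
        b = fm.build_stylized_l5(seed=42)
        np.testing.assert_array_equal(a.start, b.start)
        np.testing.assert_array_equal(a.end, b.end)

    def test_different_seed_differs(self):
        a = fm.build_stylized_l5(seed=1)
        b = fm.build_stylized_l5(seed=2)
        assert not np.allclose(a.end, b.end)

    def test_rotation_preserves_z(self, morphology):
        rot = morphology.transformed(rotation=1.234)
        np.testing.assert_allclose(rot.start[:, 2], morphology.start[:, 2])
        np.testing.assert_allclose(rot.end[:, 2], morphology.end[:, 2])

    def test_tuft_reaches_upper_electrodes(self):
        m = fm.build_stylized_l5(seed=3, soma_z=-1270.0)
        tuft_z = m.end[m.labels == "tuft", 2]
        assert tuft_z.max() > -300.0

    def test_total_extent_about_1300_um(self, morphology):
        extent = morphology.end[:, 2].max() - morphology.end[:, 2].min()
        assert 1100.0 < extent < 1600.0

    def test_swc_roundtrip(self, morphology, tmp_path):
        path = tmp_path / "cell.swc"
        morphology.to_swc(path)
        back = fm.Morphology.from_swc(path)
        assert back.n_segments == morphology.n_segments
        np.testing.assert_allclose(back.end, morphology.end, atol=1e-3)
        np.testing.assert_allclose(back.diam, morphology.diam, atol=1e-3)
        np.testing.assert_array_equal(back.parent, morphology.parent)


class TestPassiveSolver:
    def test_no_events_no_currents(self, solver):
        field = solver.solve([], T=5.0)
        assert np.all(field.currents == 0.0)

    def test_superposition_of_events(self, solver):
        e1 = fm.SynapticEvent(segment=3, weight=0.1, tau_syn=2.0, onset=1.0)
        e2 = fm.SynapticEvent(segment=3, weight=-0.04, tau_syn=0.7,
                              onset=0.3)
        both = solver.solve([e1, e2], 20.0).currents
        summed = (solver.solve([e1], 20.0).currents
                  + solver.solve([e2], 20.0).currents)
        denom = np.abs(both).max()
        assert np.abs(both - summed).max() / denom < 1e-10

    def test_current_conservation(self, solver):
        ev = fm.SynapticEvent(segment=50, weight=0.2, tau_syn=2.0)
        field = solver.solve([ev], 30.0)
        assert field.conservation_error() < 1e-8

    def test_rc_closed_form(self, soma_only):
        sol = fm.PassiveCableSolver(soma_only, fm.PassiveParams(), DT)
        j, tau_s = 0.1, 2.0
        ev = fm.SynapticEvent(segment=0, weight=j, tau_syn=tau_s)
        n_t = int(round(60.0 / DT))
        v = sol._march(sol.input_currents([ev], n_t))[0]
        t = (np.arange(n_t) + 1) * DT
        c, g = sol.c_m[0], sol.g_leak[0]
        tau_m = c / g
        v_exact = (j * tau_s * tau_m / (c * (tau_m - tau_s))
                   * (np.exp(-t / tau_m) - np.exp(-t / tau_s)))
        assert np.abs(v - v_exact).max() / np.abs(v_exact).max() < 1e-3

    def test_bad_segment_rejected(self, solver):
        ev = fm.SynapticEvent(segment=10_000, weight=0.1)
        with pytest.raises(IndexError):
            solver.solve([ev], 5.0)

    def test_impulse_convolution_equals_direct(self, solver):
        from scipy.signal import fftconvolve

        ev = fm.SynapticEvent(segment=33, weight=0.07, tau_syn=1.7,
                              onset=1.3)
        n_t = int(round(30.0 / DT))
        direct = solver.solve([ev], 30.0).currents
        resp = solver.impulse_current_responses([33], n_t)[0]
        seq = solver.event_current_sequence(ev, n_t)
        cached = fftconvolve(resp, seq[None, :], axes=1)[:, :n_t]
        assert np.abs(cached - direct).max() / np.abs(direct).max() < 1e-9


class TestLineSource:
    def test_point_source_closed_form(self, soma_only):
        e = fm.ElectrodeArray([[300.0, 0.0, 10.0]])
        v = fm.line_source_matrix(soma_only, e)[0, 0]
        assert v == pytest.approx(1e3 / (4 * np.pi * 0.3 * 300.0),
                                  rel=1e-12)

    def test_linearity_in_currents(self, morphology, solver):
        e = fm.default_electrode_array()
        ev = fm.SynapticEvent(segment=10, weight=0.1, tau_syn=2.0)
        field = solver.solve([ev], 10.0)
        lfp = fm.lfp_line_source(field, morphology, e)
        scaled = fm.lfp_line_source(
            fm.MembraneCurrentField(3.0 * field.currents, field.dt),
            morphology, e)
        assert (np.abs(scaled - 3.0 * lfp).max()
                <= 1e-12 * np.abs(lfp).max())

    def test_line_vs_dense_point_quadrature(self, morphology):
        seg = 20
        a, b = morphology.start[seg], morphology.end[seg]
        length = np.linalg.norm(b - a)
        # electrode more than one segment length away, off axis
        e = fm.ElectrodeArray([[3 * length, 7.0, float(a[2])]])
        v_line = fm.line_source_matrix(morphology, e)[0, seg]
        pts = a + (np.arange(200)[:, None] + 0.5) / 200 * (b - a)
        d = np.linalg.norm(pts - e.positions[0], axis=1)
        v_pts = (1e3 / (4 * np.pi * e.sigma * d)).mean()
        assert abs(v_line - v_pts) / abs(v_pts) < 0.01

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            fm.ElectrodeArray([[0, 0, 0]], sigma=-0.3)

    def test_apical_vs_basal_polarity_flip(self, solver, morphology):
        """A tuft input and a basal input produce opposite-sign LFP at the
        top contact."""
        e = fm.default_electrode_array()
        placed = morphology  # local coords; top electrode at z=0 is above
        tuft_seg = int(np.flatnonzero(morphology.labels == "tuft")[5])
        basal_seg = int(np.flatnonzero(morphology.labels == "basal")[5])
        shifted = morphology.transformed(dz=-1270.0)
        sol = fm.PassiveCableSolver(shifted, fm.PassiveParams(), DT)
        del placed
        lfp_t = fm.lfp_line_source(
            sol.solve([fm.SynapticEvent(tuft_seg, 0.1)], 20.0), shifted, e)
        lfp_b = fm.lfp_line_source(
            sol.solve([fm.SynapticEvent(basal_seg, 0.1)], 20.0), shifted, e)
        top = 0
        it, ib = (np.abs(lfp_t[top]).argmax(), np.abs(lfp_b[top]).argmax())
        assert np.sign(lfp_t[top, it]) == -np.sign(lfp_b[top, ib])


class TestDipole:
    def test_two_monopole_dipole(self):
        m = fm.Morphology(start=[[0, 0, 0], [0, 0, 50]],
                          end=[[0, 0, 50], [0, 0, 100]], diam=[2, 2],
                          parent=[-1, 0], labels=["soma", "trunk"])
        cur = fm.MembraneCurrentField(np.array([[1.0], [-1.0]]), dt=1.0)
        p = fm.current_dipole(cur, m).p
        np.testing.assert_allclose(p.ravel(), [0.0, 0.0, -50.0])

    def test_translation_invariance(self, morphology, solver):
        ev = fm.SynapticEvent(segment=60, weight=0.1)
        field = solver.solve([ev], 10.0)
        p0 = fm.current_dipole(field, morphology).p
        p1 = fm.current_dipole(field,
                               morphology.transformed(dz=500.0)).p
        assert np.abs(p1 - p0).max() / np.abs(p0).max() < 1e-9

    def test_nonconserved_currents_warn(self, soma_only):
        cur = fm.MembraneCurrentField(np.array([[1.0]]), dt=1.0)
        with pytest.warns(UserWarning):
            fm.current_dipole(cur, soma_only)

    def test_far_field_inverse_square(self, morphology, solver):
        ev = fm.SynapticEvent(segment=30, weight=0.1, tau_syn=2.0)
        field = solver.solve([ev], 10.0)
        p = fm.current_dipole(field, morphology).p
        k = np.argmax(np.abs(p[2]))
        extent = 1500.0
        center = morphology.midpoint.mean(axis=0)
        for r in (20 * extent, 40 * extent):
            e = fm.ElectrodeArray([center + [0.0, 0.0, r]],
                                  min_distance=1.0)
            v = fm.lfp_line_source(field, morphology, e)[0, k]
            v_dip = 1e3 * p[2, k] / (4 * np.pi * e.sigma * r ** 2)
            assert abs(v - v_dip) / abs(v_dip) < 0.05


class TestFourSphere:
    HEAD = fm.FourSphereParams()
    LOC = (0.0, 0.0, -1000.0)
    ELEC = (0.0, 0.0, 11000.0)

    def test_linearity_in_moment(self):
        w = fm.four_sphere_transfer(self.HEAD, self.LOC, self.ELEC)
        p = np.array([[1.0], [2.0], [3.0]])
        d1 = fm.DipoleTrace(p, dt=1.0)
        d2 = fm.DipoleTrace(2 * p, dt=1.0)
        v1 = fm.eeg_four_sphere(d1, self.LOC, self.HEAD)
        v2 = fm.eeg_four_sphere(d2, self.LOC, self.HEAD)
        np.testing.assert_allclose(v2, 2 * v1, rtol=1e-12)
        np.testing.assert_allclose(v1, w @ p, rtol=1e-12)

    def test_tangential_component_silent_at_vertex(self):
        w = fm.four_sphere_transfer(self.HEAD, self.LOC, self.ELEC)
        assert w[0] == pytest.approx(0.0, abs=1e-12)
        assert w[1] == pytest.approx(0.0, abs=1e-12)
        assert w[2] > 0

    def test_series_self_convergence(self):
        h_hi = dataclasses.replace(self.HEAD, n_max=300, rtol=1e-12)
        w = fm.four_sphere_transfer(self.HEAD, self.LOC, self.ELEC)
        w_hi = fm.four_sphere_transfer(h_hi, self.LOC, self.ELEC)
        assert np.abs(w - w_hi).max() / np.abs(w_hi).max() < 1e-3

    def test_location_outside_brain_rejected(self):
        with pytest.raises(ValueError):
            fm.four_sphere_transfer(self.HEAD, (0.0, 0.0, 5000.0),
                                    self.ELEC)

    def test_nonconverged_truncation_raises(self):
        h = dataclasses.replace(self.HEAD, n_max=5, rtol=1e-9)
        with pytest.raises(RuntimeError):
            fm.four_sphere_transfer(h, self.LOC, self.ELEC)

    def test_eeg_orders_of_magnitude_below_lfp(self, morphology, solver):
        ev = fm.SynapticEvent(segment=30, weight=0.1)
        shifted = morphology.transformed(dz=-1270.0)
        sol = fm.PassiveCableSolver(shifted, fm.PassiveParams(), DT)
        field = sol.solve([ev], 20.0)
        lfp = fm.lfp_line_source(field, shifted,
                                 fm.default_electrode_array())
        dip = fm.current_dipole(field, shifted)
        eeg_pv = fm.eeg_four_sphere(dip, (0, 0, -1270.0))
        # pV -> uV factor 1e-6: EEG should be far below peak LFP
        assert np.abs(eeg_pv).max() * 1e-6 < 1e-3 * np.abs(lfp).max()
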