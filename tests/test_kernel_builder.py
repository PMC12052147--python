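"""Toy and biophysical kernel construction."""

import dataclasses

import numpy as np
import pytest

from popkernel import forward_model as fm
from popkernel import kernel_builder as kb


class TestToyKernel:
    def test_peak_time_analytic(self):
        p = kb.ToyKernelParams(dt=1e-4)
        assert p.peak_time == pytest.approx(
            0.2 * 1.0 / (1.0 - 0.2) * np.log(1.0 / 0.2))
        k = kb.toy_kernel(1.0, p)
        t_num = np.argmax(k) * p.dt
        assert t_num == pytest.approx(p.peak_time, abs=2 * p.dt)
        assert k.max() <= 1.0 + 1e-12
        assert k.max() == pytest.approx(1.0, abs=1e-6)

    def test_zero_amplitude_zero_kernel(self, toy_params):
        assert np.all(kb.toy_kernel(0.0, toy_params) == 0.0)

    def test_zero_at_t_zero(self, toy_params):
        assert kb.toy_kernel(2.0, toy_params)[0] == 0.0

    def test_amplitude_scales_kernel(self, toy_params):
        w = kb.toy_kernel(1.0, toy_params)
        np.testing.assert_allclose(kb.toy_kernel(-2.5, toy_params),
                                   -2.5 * w)

    def test_equal_time_constants_rejected(self):
        with pytest.raises(ValueError):
            kb.ToyKernelParams(tau_rise=1.0, tau_decay=1.0)


class TestToyBank:
    def test_zero_sd_all_kernels_identical(self):
        p = kb.ToyKernelParams(amp_mean=1.0, amp_sd=0.0)
        bank = kb.sample_toy_bank(p, 100, seed=0)
        for k in bank.kernels[1:]:
            np.testing.assert_array_equal(k, bank.kernels[0])
        np.testing.assert_allclose(bank.population_kernel,
                                   bank.kernels[0], rtol=1e-12)
        peaks = bank.kernels.max(axis=2)
        np.testing.assert_allclose(peaks, peaks[0, 0])

    def test_sample_sd_of_peaks(self):
        p = kb.ToyKernelParams(amp_mean=1.0, amp_sd=0.5)
        bank = kb.sample_toy_bank(p, 1000, seed=1)
        amps = bank.amplitude_coefficients
        assert amps.std() == pytest.approx(0.5, rel=0.1)
        assert amps.mean() == pytest.approx(1.0, abs=0.05)

    def test_two_kernel_bank(self):
        p = kb.ToyKernelParams(amp_mean=1.0, amp_sd=0.4)
        bank = kb.sample_toy_bank(p, 2, seed=2)
        np.testing.assert_allclose(
            bank.population_kernel,
            0.5 * (bank.kernels[0] + bank.kernels[1]))

    def test_population_kernel_is_exact_mean(self):
        p = kb.ToyKernelParams(amp_sd=1.0)
        bank = kb.sample_toy_bank(p, 7, seed=3)
        np.testing.assert_array_equal(bank.population_kernel,
                                      bank.kernels.mean(axis=0))

    def test_h5_roundtrip(self, tmp_path):
        p = kb.ToyKernelParams(amp_sd=0.3)
        bank = kb.sample_toy_bank(p, 5, seed=4)
        path = tmp_path / "bank.h5"
        bank.to_h5(path)
        back = kb.KernelBank.from_h5(path)
        np.testing.assert_array_equal(back.kernels, bank.kernels)
        assert back.dt == bank.dt
        assert back.config["kind"] == "toy"


class TestPopulationSampling:
    CFG = kb.PopulationConfig(k_out=200, seed=3)

    def test_soma_depths_capped(self, morphology):
        cells = kb.sample_population_realization(self.CFG, 0, morphology)
        z = np.array([c.soma_z for c in cells])
        assert np.all(np.abs(z - self.CFG.soma_z_mean)
                      <= self.CFG.cap_sd * self.CFG.soma_z_sd)
        assert z.std() > 0.5 * self.CFG.soma_z_sd

    def test_horizontal_positions_in_disc(self, morphology):
        cells = kb.sample_population_realization(self.CFG, 0, morphology)
        r = np.array([np.hypot(c.x, c.y) for c in cells])
        assert np.all(r <= self.CFG.r_pop + 1e-9)
        # uniform on disc: mean radius = 2/3 R
        assert r.mean() == pytest.approx(2 / 3 * self.CFG.r_pop, rel=0.1)

    def test_synapse_depth_follows_weighting(self, morphology):
        cfg = dataclasses.replace(self.CFG, k_out=2000)
        cells = kb.sample_population_realization(cfg, 0, morphology)
        depth = np.array([
            morphology.midpoint[c.event.segment, 2] + c.soma_z
            for c in cells])
        assert depth.mean() == pytest.approx(cfg.syn_z_mean, abs=30.0)
        assert depth.std() < 1.8 * cfg.syn_z_sd

    def test_zero_sd_targets_single_depth_bin(self, morphology):
        cfg = dataclasses.replace(self.CFG, syn_z_sd=0.0, soma_z_sd=0.0)
        cells = kb.sample_population_realization(cfg, 0, morphology)
        segs = {c.event.segment for c in cells}
        assert len(segs) == 1

    def test_uniform_targets_all_sections(self, morphology):
        cfg = dataclasses.replace(self.CFG, uniform_synapses=True,
                                  k_out=4000)
        cells = kb.sample_population_realization(cfg, 0, morphology)
        counts = np.bincount([c.event.segment for c in cells],
                             minlength=morphology.n_segments)
        # ~ multinomial uniform: every segment hit at these sample sizes
        expected = cfg.k_out / morphology.n_segments
        assert counts.min() > 0
        assert abs(counts.mean() - expected) < 1e-9
        assert counts.std() < 3 * np.sqrt(expected)

    def test_weight_distribution_mean(self, morphology):
        cfg = dataclasses.replace(self.CFG, k_out=5000)
        cells = kb.sample_population_realization(cfg, 0, morphology)
        j = np.array([c.event.weight for c in cells])
        assert np.all(j > 0)
        assert j.mean() == pytest.approx(cfg.j_mean, rel=0.05)

    def test_impossible_weighting_rejected(self, morphology):
        cfg = dataclasses.replace(self.CFG, syn_z_mean=1e6, syn_z_sd=1.0)
        with pytest.raises(ValueError):
            kb.sample_population_realization(cfg, 0, morphology)


class TestSingleCellKernel:
    def test_kout_one_equals_single_event_response(self, small_factory):
        cfg1 = dataclasses.replace(small_factory.cfg, k_out=1)
        cells = kb.sample_population_realization(cfg1, 0,
                                                 small_factory.morphology)
        assert len(cells) == 1
        cell = cells[0]
        fast = small_factory.cell_lfp(cell)
        # direct route: place the cell, simulate, map to electrodes
        placed = small_factory.morphology.transformed(
            dz=cell.soma_z, rotation=cell.rotation, dx=cell.x, dy=cell.y)
        sol = fm.PassiveCableSolver(placed, small_factory.passive,
                                    small_factory.cfg.dt)
        field = sol.solve([cell.event], small_factory.cfg.kernel_length)
        direct = fm.lfp_line_source(field, placed,
                                    small_factory.electrodes)
        assert (np.abs(fast - direct).max()
                < 1e-9 * np.abs(direct).max())

    def test_kernel_linear_in_weights(self, small_factory):
        cells = kb.sample_population_realization(
            small_factory.cfg, 1, small_factory.morphology)
        k1 = sum(small_factory.cell_lfp(c) for c in cells)
        for c in cells:
            c.event.weight *= 2.0
        k2 = sum(small_factory.cell_lfp(c) for c in cells)
        assert np.abs(k2 - 2 * k1).max() < 1e-12 * np.abs(k1).max()

    def test_causality_before_minimum_delay(self, small_bank):
        cfg = kb.PopulationConfig(**{k: v for k, v in
                                     small_bank.config.items()
                                     if k not in ("kind",)})
        # delays are normal(1, 0.2) floored at 0: nothing before ~0.2 ms
        n_zero = int(0.2 / cfg.dt)
        assert np.abs(small_bank.kernels[:, :, :n_zero]).max() == 0.0


class TestKernelBank:
    def test_mean_consistency_bit_exact(self, small_bank):
        np.testing.assert_array_equal(small_bank.population_kernel,
                                      small_bank.kernels.mean(axis=0))

    def test_single_kernel_bank_mean(self, small_factory):
        cfg = dataclasses.replace(small_factory.cfg, n_presyn_kernels=1)
        bank = kb.KernelFactory(cfg, template=small_factory).build_bank()
        np.testing.assert_array_equal(bank.population_kernel,
                                      bank.kernels[0])

    def test_apical_basal_polarity_opposition(self, small_factory):
        cfg_ap = dataclasses.replace(small_factory.cfg, syn_z_mean=-200.0,
                                     n_presyn_kernels=3)
        cfg_ba = dataclasses.replace(small_factory.cfg, n_presyn_kernels=3)
        bank_ap = kb.KernelFactory(cfg_ap, with_eeg=False,
                                   template=small_factory).build_bank()
        bank_ba = kb.KernelFactory(cfg_ba, with_eeg=False,
                                   template=small_factory).build_bank()
        top = 0
        ka = bank_ap.population_kernel[top]
        kb_ = bank_ba.population_kernel[top]
        sa = np.sign(ka[np.abs(ka).argmax()])
        sb = np.sign(kb_[np.abs(kb_).argmax()])
        assert sa == -sb

    def test_uniform_population_kernel_weaker_everywhere(self,
                                                         small_factory):
        cfg_u = dataclasses.replace(small_factory.cfg,
                                    uniform_synapses=True,
                                    n_presyn_kernels=5)
        bank_u = kb.KernelFactory(cfg_u, with_eeg=False,
                                  template=small_factory).build_bank()
        bank_b = kb.KernelFactory(
            dataclasses.replace(small_factory.cfg, n_presyn_kernels=5),
            with_eeg=False, template=small_factory).build_bank()
        amp_u = np.abs(bank_u.population_kernel).max(axis=1)
        amp_b = np.abs(bank_b.population_kernel).max(axis=1)
        assert np.all(amp_u < amp_b)

    def test_flipped_bank_is_sign_reversed(self, small_bank):
        flip = small_bank.flipped()
        np.testing.assert_array_equal(flip.kernels, -small_bank.kernels)
        np.testing.assert_array_equal(flip.eeg_kernels,
                                      -small_bank.eeg_kernels)

    def test_table1_configuration_grid(self):
        cfgs = kb.table1_configs(kout_scale=0.1, n_presyn_kernels=2)
        assert set(cfgs) >= {"default", "apical", "uniform",
                             "narrow input region", "broad input region"}
        assert cfgs["default"].k_out == 50
        assert cfgs["large Kout"].k_out == 100
        assert cfgs["apical"].syn_z_mean == -200.0
        assert cfgs["variable synapses"].j_s == 0.8
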