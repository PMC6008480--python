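"""Recurrent network engine: currents, plasticity routing, determinism."""

import numpy as np
import pytest

from memstdp import (
    NetworkSimulator,
    NeuronParams,
    PlasticityParams,
    StimulusProgram,
    WeightMatrix,
    external_current,
    init_network,
    internal_current,
)


class TestInitNetwork:
    def test_constant_mode(self, plast_net):
        w = init_network(5, "constant", value=0.5, params=plast_net)
        off = w.offdiag()
        assert np.all(off == 0.5)

    def test_diagonal_zero_every_mode(self, plast_net):
        for mode in ("constant", "uniform-random"):
            w = init_network(6, mode, seed=3, params=plast_net)
            assert np.all(np.diag(w.omega) == 0)

    def test_uniform_random_reproducible_and_bounded(self, plast_net):
        w1 = init_network(8, "uniform-random", seed=11, params=plast_net)
        w2 = init_network(8, "uniform-random", seed=11, params=plast_net)
        assert np.array_equal(w1.omega, w2.omega)
        off = w1.offdiag()
        assert off.min() >= plast_net.omega_min and off.max() <= plast_net.omega_max

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            init_network(1)


class TestExternalCurrent:
    def test_zero_pattern(self):
        assert np.all(external_current(np.zeros(9, dtype=int), 0.43025) == 0)

    def test_amplitude_and_linearity(self):
        P = np.array([0, 1, 1, 0])
        out = external_current(P, 0.43025)
        assert out[1] == pytest.approx(0.43025)
        assert np.allclose(external_current(P, 2 * 0.43025), 2 * out)

    def test_non_binary_raises(self):
        with pytest.raises(ValueError):
            external_current(np.array([0, 2]), 1.0)


class TestInternalCurrent:
    def test_no_spikes(self):
        w = init_network(4, "constant", value=0.5)
        assert np.all(internal_current(w, [], 2.4) == 0)

    def test_single_source_normalization_cancels(self):
        """With one incoming connection, the weight cancels and the target
        receives exactly I0."""
        w = WeightMatrix(np.array([[0.0, 0.5], [0.0, 0.0]]))
        out = internal_current(w, [0], 2.4)
        assert out[1] == pytest.approx(2.4)

    def test_all_sources_deliver_exactly_I0(self):
        rng = np.random.default_rng(5)
        w = WeightMatrix(rng.uniform(0.05, 1.0, (7, 7)))
        out = internal_current(w, range(7), 2.4)
        assert np.allclose(out, 2.4)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        w = WeightMatrix(rng.uniform(0.05, 1.0, (6, 6)))
        spiking = [1, 4]
        expected = np.zeros(6)
        for j in range(6):
            denom = sum(w.omega[i, j] for i in range(6))
            expected[j] = sum(w.omega[i, j] * 2.4 / denom for i in spiking)
        assert np.allclose(internal_current(w, spiking, 2.4), expected)


class TestStimulusProgram:
    def test_segment_lookup_and_cycle(self):
        prog = StimulusProgram(
            [(10.0, np.array([1.0, 0.0])), (5.0, np.array([0.0, 2.0]))], repeats=2
        )
        assert prog.total_duration_ms == 30.0
        assert prog.current_at(3.0)[0] == 1.0
        assert prog.current_at(12.0)[1] == 2.0
        assert prog.current_at(16.0)[0] == 1.0  # second cycle
        assert np.all(prog.current_at(31.0) == 0)

    def test_invalid_segments_raise(self):
        with pytest.raises(ValueError):
            StimulusProgram([(0.0, np.zeros(2))])
        with pytest.raises(ValueError):
            StimulusProgram([])


class TestStepPlasticity:
    def _two_neuron_sim(self, leak=False):
        w = init_network(2, "constant", value=0.5)
        return NetworkSimulator(
            w,
            NeuronParams(),
            PlasticityParams(kappa=4.17e-3),
            dt_ms=0.05,
            I0_int=0.0,
            leak_between_spikes=leak,
        )

    def test_spike_onto_depolarized_partner_potentiates(self, neuron):
        """A spikes while B is high on its ramp -> omega_AB grows; B later
        spikes while A sits at rest -> omega_BA shrinks."""
        from memstdp.neuron import current_for_latency

        sim = self._two_neuron_sim()
        I_slow = current_for_latency(22.0, neuron)  # B: long ramp
        I_fast = current_for_latency(3.0, neuron)  # A: short ramp
        prog = StimulusProgram(
            [
                (10.0, np.array([0.0, I_slow])),
                (4.0, np.array([I_fast, I_slow])),
                (12.0, np.array([0.0, I_slow])),
            ]
        )
        res = sim.run(prog, 26.0)
        order = res.spike_neurons[np.argsort(res.spike_times_ms)]
        assert list(order[:2]) == [0, 1]  # A first, then B
        assert sim.w.omega[0, 1] > 0.5  # A->B potentiated (u_B > 0)
        assert sim.w.omega[1, 0] < 0.5  # B->A depressed (u_A = u_rest < 0)

    def test_no_spikes_no_change_without_leak(self):
        sim = self._two_neuron_sim(leak=False)
        before = sim.w.omega.copy()
        for _ in range(200):
            sim.step(np.zeros(2))
        assert np.array_equal(sim.w.omega, before)

    def test_leak_decays_weights_between_spikes(self):
        sim = self._two_neuron_sim(leak=True)
        for _ in range(200):
            sim.step(np.zeros(2))
        assert np.all(sim.w.offdiag() < 0.5)

    def test_locality_only_source_row_changes(self, neuron):
        """A plasticity event at source i touches only row i."""
        from memstdp.neuron import current_for_latency

        w = init_network(5, "uniform-random", seed=2)
        sim = NetworkSimulator(w, neuron, PlasticityParams(), dt_ms=0.05, I0_int=0.0)
        before = sim.w.omega.copy()
        I = np.zeros(5)
        I[2] = current_for_latency(3.0, neuron)
        spiked = set()
        for _ in range(200):
            spiked.update(sim.step(I).tolist())
        assert spiked == {2}
        changed = np.argwhere(sim.w.omega != before)
        assert changed.size > 0
        assert set(changed[:, 0]) == {2}


class TestRun:
    def test_zero_duration_returns_initial_state(self, neuron, plast_net):
        w = init_network(3, "constant", value=0.5)
        sim = NetworkSimulator(w, neuron, plast_net)
        res = sim.run(None, 0.0)
        assert res.spike_times_ms.size == 0
        assert np.array_equal(res.snapshots[0][1].omega, w.omega)

    def test_pattern_presentation_count(self):
        """Cycling four patterns every 19.2 ms over 7.2 s gives 375
        presentations."""
        from memstdp.coding import temporal_program
        from memstdp.patterns import Pattern

        pats = [
            Pattern(2, 2, np.eye(4, dtype=int)[i % 4].astype(np.uint8)) for i in range(4)
        ]
        prog = temporal_program(pats, 4, per_item_ms=19.2, loops=94, drive_current=1.0)
        assert prog.cycle_ms == pytest.approx(4 * 19.2)
        assert 7200.0 / 19.2 == pytest.approx(375.0)

    def test_determinism_identical_rasters(self, neuron, plast_net):
        from memstdp.coding import rate_program
        from memstdp.neuron import current_for_rate

        drive = current_for_rate(40.0, neuron)
        results = []
        for _ in range(2):
            w = init_network(4, "uniform-random", seed=9, params=plast_net)
            sim = NetworkSimulator(w, neuron, plast_net, leak_between_spikes=True)
            prog = rate_program(
                np.array([1, 1, 0, 0]), 300.0, drive_current=drive
            )
            results.append(sim.run(prog, 300.0))
        assert np.array_equal(results[0].spike_times_ms, results[1].spike_times_ms)
        assert np.array_equal(results[0].spike_neurons, results[1].spike_neurons)

    def test_raster_respects_refractory_contract(self, neuron, plast_net):
        from memstdp.coding import rate_program
        from memstdp.neuron import current_for_rate

        w = init_network(3, "constant", value=0.5, params=plast_net)
        sim = NetworkSimulator(w, neuron, plast_net)
        prog = rate_program(
            np.array([1, 1, 1]), 500.0, drive_current=current_for_rate(60.0, neuron)
        )
        res = sim.run(prog, 500.0)
        for i in range(3):
            t = res.spike_times_ms[res.spike_neurons == i]
            assert np.all(np.diff(t) >= neuron.t_ref_ms)


class TestWeightMatrixIO:
    def test_text_round_trip(self, tmp_path):
        w = init_network(5, "uniform-random", seed=4)
        path = tmp_path / "w.txt"
        w.save_txt(path)
        w2 = WeightMatrix.load_txt(path)
        assert np.allclose(w.omega, w2.omega, atol=1e-8)
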