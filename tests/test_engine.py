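import numpy as np
import pytest

import iwavesim as iw
from iwavesim.engine import (background_mean_counts, draw_external_input,
                             propagator_coefficients, run)
from iwavesim.stimulation import TMSPulse

from conftest import make_toy_connectome, quiet_config


class TestQuiescence:
    def test_no_input_stays_at_rest(self):
        conn = make_toy_connectome(5)
        cfg = quiet_config(duration=50.0)
        rec = run(conn, cfg, [], dynamics_seed=0, backend="numpy",
                  record_voltages=True)
        assert rec.n_spikes == 0
        v = rec.meta["voltage_trace"]
        assert np.allclose(v, cfg.neuron.V_r)

    def test_subthreshold_decay_to_rest(self):
        conn = make_toy_connectome(4)
        cfg = quiet_config(duration=100.0)
        cfg.sim.init_voltage = "uniform"
        rec = run(conn, cfg, [], dynamics_seed=3, backend="numpy",
                  record_voltages=True)
        assert rec.n_spikes == 0
        v = rec.meta["voltage_trace"]
        # after 10 tau_m everything has relaxed to V_r
        assert np.allclose(v[-1], cfg.neuron.V_r, atol=1e-3)


class TestSynapticDelivery:
    def test_single_spike_delivery_timing_and_decay(self):
        """A presynaptic spike increments the target's synaptic current
        exactly `delay` after the spike, then it decays with tau_syn."""
        delay = 1.3
        cfg = quiet_config(duration=20.0)
        conn = make_toy_connectome(
            2, pre=[0], post=[1], weight=[500.0], delay=[delay],
            positions=[[0, 0, 0.0], [0, 0, 2.3]])
        # floor 0: the neuron at full depth receives no current at all
        pulse = TMSPulse(onset_ms=5.0, proportion=1.0, depth_floor=0.0)
        rec = run(conn, cfg, [pulse], dynamics_seed=0, backend="numpy",
                  record_voltages=True)
        assert rec.n_spikes == 1
        t_spike = rec.time_ms[0]
        assert t_spike == pytest.approx(5.1)          # end of the onset step
        v1 = rec.meta["voltage_trace"][:, 1]
        moved = np.flatnonzero(np.abs(v1 - cfg.neuron.V_r) > 1e-12)
        # I_syn jumps at t_spike + delay; V reflects it one step later,
        # i.e. at trace index (t_spike + delay)/dt.
        expected_first = int(round((t_spike + delay) / cfg.sim.dt))
        assert moved[0] == expected_first
        # response decays back toward rest afterwards
        peak = np.argmax(v1)
        assert np.all(np.diff(v1[peak + 50:]) <= 1e-12)

    def test_event_conservation_through_delay_queue(self, tiny_cfg, tiny_net):
        cfg = iw.make_fixture_config(0.05, seed=1234)
        cfg.sim.duration = 100.0
        rec = run(tiny_net, cfg, [], dynamics_seed=5)
        out_degree = np.bincount(tiny_net.pre, minlength=tiny_net.n_neurons)
        expected = int(out_degree[rec.neuron].sum())
        assert rec.meta["events_scheduled"] == expected
        assert rec.meta["events_delivered"] <= rec.meta["events_scheduled"]

    def test_all_scheduled_events_delivered_when_window_allows(self):
        # spike early, delays short, simulation long: nothing is lost
        cfg = quiet_config(duration=30.0)
        conn = make_toy_connectome(
            3, pre=[0, 0], post=[1, 2], weight=[100.0, 100.0],
            delay=[0.5, 1.0],
            positions=[[0, 0, 0.0], [0, 0, 2.3], [0, 0, 2.3]])
        rec = run(conn, cfg,
                  [TMSPulse(onset_ms=5.0, proportion=1.0, depth_floor=0.0)],
                  dynamics_seed=0, backend="numpy")
        assert rec.meta["events_scheduled"] == 2
        assert rec.meta["events_delivered"] == 2


class TestIntegratorAccuracy:
    @staticmethod
    def _impulse_response(t, t0, w, p):
        """Closed-form V(t) after I_syn jumps by w at time t0 (V(t0)=V_r)."""
        s = np.maximum(t - t0, 0.0)
        coeff = w * p.tau_syn * p.tau_m / ((p.tau_m - p.tau_syn) * p.C_m)
        return p.V_r + coeff * (np.exp(-s / p.tau_m) - np.exp(-s / p.tau_syn)) \
            * (t > t0)

    def _drive(self, dt, integrator, amp):
        rng = np.random.default_rng(42)
        n = 10
        pre = [0] * (n - 1)
        post = list(range(1, n))
        weight = rng.uniform(100, 400, n - 1)
        delay = np.round(rng.uniform(0.5, 3.0, n - 1), 1)
        positions = np.zeros((n, 3))
        positions[1:, 2] = 2.3        # only neuron 0 is stimulated
        cfg = quiet_config(duration=50.0)
        cfg.sim.dt = dt
        cfg.sim.integrator = integrator
        rec = run(make_toy_connectome(n, pre, post, weight, delay, dt=dt,
                                      positions=positions),
                  cfg, [TMSPulse(onset_ms=5.0, proportion=1.0,
                                 surface_amplitude_pA=amp, depth_floor=0.0)],
                  dynamics_seed=0, backend="numpy", record_voltages=True)
        v = rec.meta["voltage_trace"]
        times = (np.arange(v.shape[0]) + 1) * dt
        t_spike = rec.time_ms[rec.neuron == 0][0]
        return cfg, weight, delay, times, v, t_spike

    def test_exact_update_reproduces_closed_form(self):
        """The per-step exponential propagator reproduces the analytic
        post-synaptic impulse response at grid points to machine precision."""
        cfg, weight, delay, times, v, t_spike = self._drive(0.1, "exact", 2e5)
        p = cfg.neuron
        for i in range(1, 10):
            ref = self._impulse_response(times, t_spike + delay[i - 1],
                                         weight[i - 1], p)
            # limited only by float32 weight storage (~1e-7 relative)
            assert np.abs(v[:, i] - ref).max() < 1e-6

    def test_fine_euler_oracle_converges_to_exact_solution(self):
        """Brute-force forward Euler at dt/100 agrees with the exponential
        update's trajectory (via the shared closed form) to <0.1%."""
        # one-step pulses deposit charge amp*dt: 100x amplitude keeps the
        # stimulus identical at dt/100
        cfg, weight, delay, times, v, t_spike = self._drive(0.001, "euler", 2e7)
        p = cfg.neuron
        worst = 0.0
        for i in range(1, 10):
            ref = self._impulse_response(times, t_spike + delay[i - 1],
                                         weight[i - 1], p)
            scale = np.abs(ref - p.V_r).max()
            worst = max(worst, np.abs(v[:, i] - ref).max() / scale)
        assert worst < 1e-3

    def test_steady_state_under_constant_rate_drive(self):
        """Mean depolarisation under steady Poisson drive matches the
        closed-form mean current I = K r w tau_syn through V = V_r + I tau_m/C_m."""
        n = 200
        conn = make_toy_connectome(n)
        cfg = quiet_config(duration=300.0)
        cfg.external.rate_hz = 8.0
        cfg.external.k_ext_exc = 50          # weak enough to stay subthreshold
        cfg.sim.init_voltage = "reset"
        rec = run(conn, cfg, [], dynamics_seed=8, backend="numpy",
                  record_voltages=True)
        assert rec.n_spikes == 0
        p = cfg.neuron
        i_mean = 50 * 8.0 * (p.g_e * p.w) * (p.tau_syn * 1e-3)    # pA
        v_pred = p.V_r + i_mean * p.tau_m / p.C_m
        v_obs = rec.meta["voltage_trace"][1000:].mean()
        assert v_obs == pytest.approx(v_pred, rel=0.02)


class TestRefractoriness:
    def test_isi_floor_under_strong_drive(self):
        n = 50
        conn = make_toy_connectome(n)
        cfg = quiet_config(duration=100.0)
        cfg.external.rate_hz = 8.0
        cfg.external.k_ext_exc = 4000        # strong suprathreshold drive
        rec = run(conn, cfg, [], dynamics_seed=1)
        assert rec.n_spikes > n              # everyone fires repeatedly
        for i in range(n):
            t = np.sort(rec.time_ms[rec.neuron == i])
            if len(t) > 1:
                assert np.diff(t).min() > cfg.neuron.tau_ref

    def test_refractory_period_sets_max_rate(self):
        conn = make_toy_connectome(20)
        rates = []
        for tau_ref in (1.0, 2.0):
            cfg = quiet_config(duration=200.0)
            cfg.neuron.tau_ref = tau_ref
            cfg.external.rate_hz = 8.0
            cfg.external.k_ext_exc = 8000
            rec = run(conn, cfg, [], dynamics_seed=2)
            rates.append(rec.n_spikes)
        assert rates[0] > rates[1]           # shorter refractoriness, more spikes


class TestDeterminismAndBackends:
    def test_identical_seeds_identical_records(self, tiny_cfg, tiny_net):
        cfg = iw.make_fixture_config(0.05, seed=1234)
        cfg.sim.duration = 60.0
        a = run(tiny_net, cfg, [], dynamics_seed=9)
        b = run(tiny_net, cfg, [], dynamics_seed=9)
        assert np.array_equal(a.neuron, b.neuron)
        assert np.array_equal(a.time_ms, b.time_ms)
        c = run(tiny_net, cfg, [], dynamics_seed=10)
        assert not (len(c.neuron) == len(a.neuron)
                    and np.array_equal(a.neuron, c.neuron))

    def test_numba_and_numpy_backends_agree(self, tiny_net):
        cfg = iw.make_fixture_config(0.05, seed=1234)
        cfg.sim.duration = 40.0
        cfg.sim.analysis_start = 0.0
        pulses = [TMSPulse(onset_ms=20.0, proportion=0.25)]
        a = run(tiny_net, cfg, pulses, dynamics_seed=3, backend="numba")
        b = run(tiny_net, cfg, pulses, dynamics_seed=3, backend="numpy")
        assert np.array_equal(a.neuron, b.neuron)
        assert np.array_equal(a.time_ms, b.time_ms)


class TestExternalInput:
    def test_poisson_mean(self):
        lam = np.full(1000, 1.6)
        counts = draw_external_input(lam, 1000, rng=12)     # 10^6 draws
        assert counts.shape == (1000, 1000)
        assert abs(counts.mean() - 1.6) / 1.6 < 0.01

    def test_zero_rate_all_zero(self):
        counts = draw_external_input(np.zeros(10), 100, rng=0)
        assert counts.sum() == 0

    def test_group_specific_fibre_counts(self, tiny_cfg, tiny_net):
        lam = background_mean_counts(tiny_cfg, tiny_net)
        dt_s = tiny_cfg.sim.dt * 1e-3
        exc = tiny_net.group_indices("2/3E")
        inh = tiny_net.group_indices("5I")
        pm = tiny_net.group_indices("PM")
        assert np.allclose(lam[exc], 2000 * 8.0 * dt_s)   # = 1.6
        assert np.allclose(lam[inh], 1850 * 8.0 * dt_s)   # = 1.48
        assert np.allclose(lam[pm], 0.0)
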