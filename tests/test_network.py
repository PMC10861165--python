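import numpy as np
import pytest
from scipy import stats

import iwavesim as iw
from iwavesim.config import (CONNECTION_PROBABILITY, FULL_SCALE_COUNTS,
                             GROUP_LAYERS, GROUP_NAMES, GROUP_SIGNS, Geometry,
                             ModelConfig)
from iwavesim.network import (ConstructionError, assign_delays,
                              compute_synapse_count, connection_radius_mm,
                              place_neurons, sample_connections)

FULL_COUNTS = np.array([FULL_SCALE_COUNTS[g] for g in GROUP_NAMES])


class TestSynapseCount:
    def test_zero_probability_gives_zero(self):
        assert compute_synapse_count(0.0, 10332, 10944) == 0

    def test_single_synapse_identity(self):
        # C_a = 1/(N_pre*N_post) corresponds to exactly one placement
        for n_pre, n_post in [(50, 60), (7, 7), (1000, 10)]:
            assert compute_synapse_count(1 / (n_pre * n_post), n_pre, n_post) == 1

    def test_frozen_high_precision_value(self):
        # 40-digit arbitrary-precision evaluation, frozen as a regression value
        assert compute_synapse_count(0.192, 10332, 10332) == 22758424

    def test_published_totals(self):
        total = 0
        for t in range(8):
            for s in range(8):
                total += compute_synapse_count(
                    CONNECTION_PROBABILITY[t, s],
                    int(FULL_COUNTS[s]), int(FULL_COUNTS[t]))
        assert total == 160966761          # > 160 million
        mean = total / 38556
        # printed mean connection count is 4,176; tables give 4174.88
        assert abs(mean - 4176) / 4176 < 1e-3

    @pytest.mark.parametrize("bad", [1.0, 1.5, -0.1])
    def test_invalid_probability_rejected(self, bad):
        with pytest.raises(ValueError):
            compute_synapse_count(bad, 10, 10)

    def test_monotone_in_probability(self):
        ks = [compute_synapse_count(c, 500, 400)
              for c in (0.0, 0.1, 0.3, 0.6, 0.9)]
        assert ks == sorted(ks)
        assert ks[0] == 0


class TestPlacement:
    def test_z_within_layer_bands(self, tiny_cfg, tiny_net):
        bounds = tiny_cfg.geometry.layer_bounds
        for g in GROUP_NAMES:
            lo, hi = bounds[GROUP_LAYERS[g]]
            z = tiny_net.positions[tiny_net.group_indices(g), 2]
            assert np.all(z >= lo) and np.all(z <= hi)

    def test_same_seed_identical(self):
        geo = Geometry()
        counts = {g: 50 for g in GROUP_NAMES}
        a = place_neurons(counts, geo, 42)
        b = place_neurons(counts, geo, 42)
        assert np.array_equal(a, b)
        c = place_neurons(counts, geo, 43)
        assert not np.array_equal(a, c)

    def test_xy_uniform_ks(self):
        counts = {g: 1250 for g in GROUP_NAMES}   # 10^4 neurons
        pos = place_neurons(counts, Geometry(), 7)
        for axis in (0, 1):
            p = stats.kstest(pos[:, axis], "uniform").pvalue
            assert p > 0.01


class TestConnectionSampling:
    def _positions(self, n, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 1, size=(n, 3))
        return pos

    def test_exact_count_and_no_autapses(self):
        pos = self._positions(80, 0)
        pre, post = sample_connections(pos, pos, 5000, 0.3, seed=3,
                                       same_group=True)
        assert len(pre) == 5000
        assert np.all(pre != post)

    def test_zero_pairs(self):
        pos = self._positions(10, 0)
        pre, post = sample_connections(pos, pos, 0, 0.3, seed=3)
        assert len(pre) == 0

    def test_multapse_cap_error(self):
        pos = self._positions(5, 0)
        with pytest.raises(ConstructionError):
            sample_connections(pos, pos, 10_000, 0.3, seed=3,
                               max_multapse_factor=2.0)

    def test_distance_law_matches_enumeration(self):
        """Sampled pre-post pairs follow exp(-d^2/2r^2) acceptance, checked
        against exhaustive enumeration of all pair weights (chi-squared)."""
        radius = 0.25
        pos_pre = self._positions(100, 1)
        pos_post = self._positions(100, 2)
        n_pairs = 40_000
        pre, post = sample_connections(pos_pre, pos_post, n_pairs, radius, seed=9)
        d_sampled = np.hypot(pos_pre[pre, 0] - pos_post[post, 0],
                             pos_pre[pre, 1] - pos_post[post, 1])
        # brute-force law over all 10^4 ordered pairs
        dx = pos_pre[:, 0][:, None] - pos_post[None, :, 0]
        dy = pos_pre[:, 1][:, None] - pos_post[None, :, 1]
        d_all = np.hypot(dx, dy).ravel()
        w_all = np.exp(-d_all**2 / (2 * radius**2))
        edges = np.quantile(d_all, np.linspace(0, 1, 11))
        edges[0], edges[-1] = 0.0, np.inf
        expected = np.histogram(d_all, bins=edges, weights=w_all)[0]
        expected = expected / expected.sum() * n_pairs
        observed = np.histogram(d_sampled, bins=edges)[0].astype(float)
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_connection_probability_semantics(self):
        """With a flat spatial law, the chance an ordered pair is connected at
        least once reproduces C_a (Peters' rule round trip)."""
        c_a = 0.2
        n = 100
        k = compute_synapse_count(c_a, n, n)
        pos = self._positions(n, 5)
        pre, post = sample_connections(pos, pos, k, radius_mm=50.0, seed=11,
                                       same_group=False)
        connected = len(set(zip(pre.tolist(), post.tolist())))
        assert abs(connected / n**2 - c_a) < 0.05 * c_a + 0.01


class TestRadiusClasses:
    def test_class_resolution(self):
        cfg = ModelConfig()
        assert connection_radius_mm(cfg, "2/3E", "2/3E") == 0.300
        assert connection_radius_mm(cfg, "6E", "6E") == 0.225
        assert connection_radius_mm(cfg, "5E", "2/3E") == 0.050
        for tgt in ("2/3E", "5E", "6E"):
            assert connection_radius_mm(cfg, tgt, "4I") == 0.175


class TestDelays:
    def test_zero_width_gives_exact_mean(self):
        d = assign_delays(1000, 1.5, 0.0, 0.1, seed=0)
        assert np.all(d == 1.5)

    def test_floor_and_grid(self):
        d = assign_delays(100_000, 0.8, 0.5, 0.1, seed=1)
        assert d.min() >= 0.1 - 1e-12
        steps = d / 0.1
        assert np.allclose(steps, np.round(steps), atol=1e-9)

    def test_monte_carlo_mean_within_one_percent(self):
        d = assign_delays(100_000, 1.5, 0.5, 0.1, seed=2)
        assert abs(d.mean() - 1.5) / 1.5 < 0.01


class TestBuild:
    def test_pair_counts_equal_peters_rule_exactly(self, tiny_cfg, tiny_net):
        counts = tiny_cfg.counts_array
        pair = tiny_net.pair_counts()
        for t in range(8):
            for s in range(8):
                expected = compute_synapse_count(
                    CONNECTION_PROBABILITY[t, s], int(counts[s]), int(counts[t]))
                assert pair[t, s] == expected

    def test_no_autapses_and_weight_signs(self, tiny_net):
        assert np.all(tiny_net.pre != tiny_net.post)
        _, src = tiny_net.synapse_group_pair()
        for gid, name in enumerate(tiny_net.group_names):
            w = tiny_net.weight[src == gid]
            if not len(w):
                continue
            if GROUP_SIGNS.get(name, "excitatory") == "inhibitory":
                assert np.all(w < 0)
            else:
                assert np.all(w > 0)

    def test_delays_at_least_one_step(self, tiny_net):
        assert tiny_net.delay_ms.min() >= tiny_net.dt - 1e-9

    def test_structure_seed_reproducible(self):
        a = iw.make_fixture_network(0.03, seed=5)
        b = iw.make_fixture_network(0.03, seed=5)
        assert np.array_equal(a.pre, b.pre)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.delay_ms, b.delay_ms)

    def test_zero_probability_matrix_gives_empty_connectome(self):
        cfg = iw.make_fixture_config(0.03, seed=1)
        cfg.connectivity.conn_prob = np.zeros((8, 8)).tolist()
        cfg.premotor.enabled = False
        conn = iw.build_network(cfg)
        assert conn.n_synapses == 0
        assert conn.n_neurons == sum(cfg.group_counts.values())


class TestPersistence:
    def test_csv_round_trip_bit_identical(self, tiny_net, tmp_path):
        path = tmp_path / "net"
        iw.save_connectome(tiny_net, path)
        again = iw.load_connectome(path)
        for attr in ("pre", "post", "weight", "delay_ms", "positions",
                     "group_of", "group_counts", "background_mask"):
            assert np.array_equal(getattr(tiny_net, attr), getattr(again, attr))
        assert again.group_names == tiny_net.group_names

    def test_hdf5_round_trip_bit_identical(self, tiny_net, tmp_path):
        path = str(tmp_path / "net.h5")
        iw.save_connectome(tiny_net, path)
        again = iw.load_connectome(path)
        for attr in ("pre", "post", "weight", "delay_ms", "positions"):
            assert np.array_equal(getattr(tiny_net, attr), getattr(again, attr))

    def test_autapse_row_rejected(self, tiny_net, tmp_path):
        import pandas as pd
        path = tmp_path / "net"
        iw.save_connectome(tiny_net, path)
        syn = pd.read_csv(path / "synapses.csv")
        syn.loc[3, "post"] = syn.loc[3, "pre"]
        syn.to_csv(path / "synapses.csv", index=False)
        with pytest.raises(iw.ConnectomeFormatError, match="row 3"):
            iw.load_connectome(path)

    def test_negative_delay_rejected(self, tiny_net, tmp_path):
        import pandas as pd
        path = tmp_path / "net"
        iw.save_connectome(tiny_net, path)
        syn = pd.read_csv(path / "synapses.csv")
        syn.loc[0, "delay_ms"] = -0.5
        syn.to_csv(path / "synapses.csv", index=False)
        with pytest.raises(iw.ConnectomeFormatError, match="row 0"):
            iw.load_connectome(path)
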