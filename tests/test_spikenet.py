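"""Network construction, integration, statistics and instability detection."""
import numpy as np
import pytest

from homeoplast.params import (NetworkConfig, NeuronParams, TripletParams,
                               HomeostasisConfig, ConfigurationError,
                               scaled_network)
from homeoplast.plasticity import TripletSynapse
from homeoplast.spikenet import (build_network, simulate, population_rate,
                                 isi_statistics, detect_instability,
                                 epsp_probe, SpikeRaster)
from homeoplast.synthdata import poisson_trains, regular_train, TrainSpec
from conftest import make_pair_network


def tiny_config(**kw):
    base = dict(N_exc=200, N_inh=50, N_ext=100, ext_rate=2.0,
                p_conn=0.1, p_ext=0.1, seed=5)
    base.update(kw)
    return NetworkConfig(**base)


class TestBuildNetwork:
    def test_mean_in_degree_matches_binomial_expectation(self):
        cfg = tiny_config(N_exc=800, p_conn=0.05)
        net = build_network(cfg)
        deg = net.ee_in_degrees()
        expect = (cfg.N_exc - 1) * cfg.p_conn
        se = np.sqrt(expect * (1 - cfg.p_conn) / cfg.N_exc)
        assert abs(deg.mean() - expect) < 4 * se

    def test_no_connectivity_gives_empty_graph(self):
        net = build_network(tiny_config(p_conn=0.0, p_ext=0.0))
        assert net.ee.nnz == net.ei.nnz == net.ie.nnz == net.ii.nnz == 0
        assert np.all(net.ee_in_degrees() == 0)

    def test_seeded_edge_set_is_reproducible(self):
        cfg = tiny_config(N_exc=100, p_conn=0.05)
        a = build_network(cfg, seed=3)
        b = build_network(cfg, seed=3)
        assert np.array_equal(a.ee.indices, b.ee.indices)
        assert np.array_equal(a.ee.indptr, b.ee.indptr)
        c = build_network(cfg, seed=4)
        assert not np.array_equal(a.ee.indices, c.ee.indices)

    def test_no_self_connections(self):
        net = build_network(tiny_config(p_conn=0.5))
        assert all(net.ee[i, i] == 0 for i in range(20))
        assert all(net.ii[i, i] == 0 for i in range(20))

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            NetworkConfig(p_conn=1.5)
        with pytest.raises(ConfigurationError):
            NetworkConfig(N_exc=0)


class TestSimulateEquilibria:
    def test_isolated_network_at_rest_stays_at_rest(self):
        cfg = tiny_config(N_exc=50, N_inh=10, ext_rate=0.0)
        net = build_network(cfg)
        res = simulate(net, duration=0.5, seed=1, init="rest",
                       record_raster=(50, 10))
        assert res.raster.times.size == 0
        assert np.allclose(res.final_state["V"], NeuronParams().E_rest)
        assert np.all(res.final_state["g_ampa"] == 0)

    def test_constant_suprathreshold_drive_fires_periodically(self):
        # quasi-constant excitatory conductance from a very fast scheduled
        # source: the deterministic limit has vanishing ISI variability
        cfg = tiny_config(N_exc=1, N_inh=1, N_ext=1, p_conn=0.0, p_ext=1.0,
                          w_ext=0.6)
        net = build_network(cfg)
        t = np.arange(0.0, 3.0, 1e-3)  # 1 kHz regular source
        res = simulate(net, duration=3.0, seed=1, init="rest",
                       ext_schedule=(t, np.zeros(t.size, dtype=int)),
                       record_raster=(1, 0))
        st = isi_statistics(res.raster, min_spikes=3)
        assert st.rates[0] > 5.0
        assert st.cv[0] < 0.05

    def test_seeded_runs_are_bit_reproducible(self):
        cfg = tiny_config()
        net = build_network(cfg)
        a = simulate(net, duration=1.0, seed=9, record_raster=(200, 50))
        b = simulate(net, duration=1.0, seed=9, record_raster=(200, 50))
        assert np.array_equal(a.raster.times, b.raster.times)
        assert np.array_equal(a.raster.ids, b.raster.ids)
        assert np.array_equal(a.final_state["V"], b.final_state["V"])

    def test_voltages_stay_within_reversal_bounds(self):
        cfg = scaled_network(10, seed=2)
        net = build_network(cfg)
        res = simulate(net, duration=2.0, seed=2, record_raster=0)
        np_ = NeuronParams()
        V = res.final_state["V"]
        assert np.all(V >= np_.E_inh_rev) and np.all(V <= np_.E_exc_rev)
        for g in ("g_ampa", "g_nmda", "g_gaba"):
            assert np.all(res.final_state[g] >= 0)

    def test_halving_dt_changes_spike_count_by_under_two_percent(self):
        # deterministic single-neuron limit cycle driven by a fixed schedule
        cfg = tiny_config(N_exc=1, N_inh=1, N_ext=1, p_conn=0.0, p_ext=1.0,
                          w_ext=0.6)
        net = build_network(cfg)
        t = np.arange(0.0, 5.0, 1e-3)
        src = np.zeros(t.size, dtype=int)
        counts = []
        for dt in (1e-4, 5e-5):
            res = simulate(net, duration=5.0, dt=dt, seed=1, init="rest",
                           ext_schedule=(t, src), record_raster=(1, 0))
            counts.append(res.raster.times.size)
        assert counts[0] > 20
        assert abs(counts[0] - counts[1]) / counts[1] < 0.02


class TestKernelPlasticityEquivalence:
    def test_network_kernel_matches_event_driven_engine(self):
        # two neurons, one plastic synapse; spikes forced by strong
        # scheduled external inputs, then replayed through the reference
        # event-driven engine
        net = make_pair_network()
        tp = TripletParams(eta=20.0, w0=0.16)
        homeo = HomeostasisConfig(variant="metaplastic_ltd", tau_bar=0.5)
        pre_drive = np.array([0.050, 0.080, 0.230, 0.500, 0.740])
        post_drive = np.array([0.060, 0.095, 0.260, 0.290, 0.760])
        times = np.concatenate([pre_drive, post_drive])
        srcs = np.concatenate([np.zeros(pre_drive.size, dtype=int),
                               np.ones(post_drive.size, dtype=int)])
        res = simulate(net, duration=1.0, seed=1, init="rest",
                       plasticity=(tp, homeo), record_raster=(2, 0),
                       ext_schedule=(times, srcs))
        spikes_pre = res.raster.times[res.raster.ids == 0]
        spikes_post = res.raster.times[res.raster.ids == 1]
        assert spikes_pre.size and spikes_post.size
        assert not np.intersect1d(np.round(spikes_pre, 9),
                                  np.round(spikes_post, 9)).size
        syn = TripletSynapse(tp, tau_bar=homeo.tau_bar, beta=homeo.beta)
        syn.pre.r_bar = tp.kappa
        syn.post.r_bar = tp.kappa  # kernel initialises the estimate at kappa
        syn.run(spikes_pre, spikes_post)
        assert res.final_weights[0] == pytest.approx(syn.w, abs=1e-12)


class TestPopulationRate:
    def _fixture_raster(self):
        times = np.array([0.1, 0.2, 0.35, 0.4, 0.55, 0.8, 1.1, 1.4, 1.45, 1.9])
        ids = np.array([0, 1, 2, 0, 3, 4, 1, 0, 2, 4])
        return SpikeRaster(times=times, ids=ids, duration=2.0,
                           n_exc_total=5, n_inh_total=0,
                           n_exc_recorded=5, n_inh_recorded=0)

    def test_empty_raster_gives_zero_trace(self):
        r = SpikeRaster(np.empty(0), np.empty(0, dtype=int), 1.0, 5, 0, 5, 0)
        _, rates = population_rate(r, window=0.5)
        assert np.all(rates == 0)

    def test_one_spike_per_neuron_per_second_is_one_hertz(self):
        times = np.linspace(0.05, 0.95, 5)
        r = SpikeRaster(times, np.arange(5), 1.0, 5, 0, 5, 0)
        _, rates = population_rate(r, window=1.0)
        assert rates[0] == pytest.approx(1.0)

    def test_matches_hand_counted_histogram(self):
        r = self._fixture_raster()
        t, rates = population_rate(r, window=1.0)
        # first second: 6 spikes over 5 neurons; second second: 4 spikes
        assert np.allclose(rates, [6 / 5, 4 / 5])

    def test_empty_population_is_an_error(self):
        r = self._fixture_raster()
        with pytest.raises(ConfigurationError):
            population_rate(r, window=1.0, population="inh")


class TestISIStatistics:
    def test_poisson_train_has_unit_cv(self):
        trains = poisson_trains(TrainSpec(10.0, 200.0, seed=13), n=20)
        times = np.concatenate(trains)
        ids = np.concatenate([np.full(t.size, i) for i, t in enumerate(trains)])
        order = np.argsort(times)
        r = SpikeRaster(times[order], ids[order], 200.0, 20, 0, 20, 0)
        st = isi_statistics(r)
        assert st.cv.mean() == pytest.approx(1.0, abs=0.05)
        assert st.rates.mean() == pytest.approx(10.0, rel=0.05)

    def test_regular_train_has_zero_cv(self):
        t = regular_train(5.0, 20.0)
        r = SpikeRaster(t, np.zeros(t.size, dtype=int), 20.0, 1, 0, 1, 0)
        st = isi_statistics(r)
        assert st.cv[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_per_neuron_computation(self):
        rng = np.random.default_rng(5)
        trains = {i: np.sort(rng.uniform(0, 10.0, size=rng.integers(2, 30)))
                  for i in range(6)}
        times = np.concatenate(list(trains.values()))
        ids = np.concatenate([np.full(t.size, i) for i, t in trains.items()])
        order = np.argsort(times, kind="stable")
        r = SpikeRaster(times[order], ids[order], 10.0, 6, 0, 6, 0)
        st = isi_statistics(r, min_spikes=3)
        expected_cv = []
        expected_isis = 0
        for i, t in trains.items():
            d = np.diff(t)
            expected_isis += d.size
            if t.size >= 3:
                expected_cv.append(d.std() / d.mean())
        assert st.isis.size == expected_isis
        assert np.allclose(np.sort(st.cv), np.sort(expected_cv))

    def test_all_silent_raster_is_flagged(self):
        r = SpikeRaster(np.empty(0), np.empty(0, dtype=int), 1.0, 5, 0, 5, 0)
        with pytest.warns(RuntimeWarning):
            st = isi_statistics(r)
        assert st.all_silent and st.cv.size == 0


class TestDetectInstability:
    def test_constant_rate_is_stable_for_the_whole_duration(self):
        t = np.arange(1, 201.0)
        res = detect_instability(t, np.full(200, 3.0))
        assert res.outcome == "stable" and res.lifetime == 200.0

    def test_ramp_crossing_the_upper_bound_is_runaway(self):
        t = np.arange(1, 201.0)
        rates = np.where(t < 100, 3.0, 3.0 + (t - 99) * 2.0)
        res = detect_instability(t, rates, upper_bound=30.0)
        assert res.outcome == "runaway"
        assert res.lifetime == pytest.approx(113.0, abs=1.0)

    def test_decaying_rate_is_classified_silent(self):
        t = np.arange(1, 101.0)
        rates = 3.0 * np.exp(-t / 10.0)
        res = detect_instability(t, rates, lower_bound=0.1, quiet_window=10.0)
        assert res.outcome == "silent"
        assert res.lifetime < 50.0

    def test_bounds_must_be_ordered(self):
        with pytest.raises(ConfigurationError):
            detect_instability(np.arange(5.0), np.ones(5), lower_bound=2.0,
                               upper_bound=1.0)


class TestEPSP:
    def test_zero_weight_gives_no_deflection(self):
        _, v = epsp_probe(weight=0.0)
        assert np.all(v == 0)

    def test_pure_ampa_has_no_slow_tail(self):
        p_mix = NeuronParams()
        p_ampa = NeuronParams(alpha_nmda=1.0)
        t, v_mix = epsp_probe(p_mix, weight=0.16, duration=0.45,
                              spike_time=0.05)
        _, v_ampa = epsp_probe(p_ampa, weight=0.16, duration=0.45,
                               spike_time=0.05)
        late = t > 0.25  # 200 ms after the spike
        assert np.max(np.abs(v_ampa[late])) < 0.02 * np.max(v_ampa)
        assert np.max(np.abs(v_mix[late])) > 0.05 * np.max(v_mix)

    def test_peak_converges_with_a_refined_time_step(self):
        _, v = epsp_probe(weight=0.16, dt=1e-4)
        _, v_ref = epsp_probe(weight=0.16, dt=1e-6)
        # forward Euler at 0.1 ms carries a few-percent first-order error
        # on the 5 ms AMPA rise; the refined-step reference pins it down
        assert v.max() == pytest.approx(v_ref.max(), rel=0.05)
        assert 0.5e-3 < v.max() < 5e-3  # EPSP of order a millivolt


class TestBackgroundState:
    def test_scaled_network_sits_in_the_asynchronous_irregular_state(self):
        cfg = scaled_network(5, seed=4)
        net = build_network(cfg)
        res = simulate(net, duration=8.0, warmup=2.0, seed=4,
                       record_raster=(1000, 0))
        rate = res.rates.exc.mean()
        assert 1.5 < rate < 4.5          # low-rate balanced activity
        st = isi_statistics(res.raster)
        assert 0.7 < st.cv.mean() < 1.3  # irregular firing
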