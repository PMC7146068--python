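"""Single-neuron dynamics, alpha filters, drivers, partition equivalence."""

import math

import numpy as np
import pytest

import cbsim
from cbsim.engine import Simulator, alpha_kernel_value
from tests.conftest import isolated_population_graph


def lif_isi(p):
    """Closed-form pacemaker period of a LIF under constant drive."""
    return p.t_ref + p.tau_m * math.log(p.i_ex / (p.i_ex - (p.theta - p.e_rest)))


# ---------------------------------------------------------------------------
# init_state
# ---------------------------------------------------------------------------

class TestInitState:
    def test_resting_potentials_and_zero_filters(self, small_graph):
        state = cbsim.init_state(small_graph)
        assert np.all(state.populations["PC"].v == -70.0)
        assert np.all(state.populations["GR"].v == -58.0)
        for st in state.populations.values():
            assert np.all(st.g_stack == 0.0) and np.all(st.h_stack == 0.0)
            assert np.all(st.refrac == 0)

    def test_channels_deduplicated(self, small_graph):
        state = cbsim.init_state(small_graph)
        # GR receives mossy AMPA and Golgi GABA_A (10 ms): exactly 2 channels
        kinds = {(c.kind, c.tau_syn) for c in state.populations["GR"].channels}
        assert kinds == {("AMPA", 2.0), ("GABA_A", 10.0)}
        # PC: AMPA (granule + climbing fiber) shares one channel, plus GABA_A
        kinds = {(c.kind, c.tau_syn) for c in state.populations["PC"].channels}
        assert kinds == {("AMPA", 2.0), ("GABA_A", 2.0)}


# ---------------------------------------------------------------------------
# alpha kernel and filter recurrence
# ---------------------------------------------------------------------------

class TestAlphaKernel:
    def test_closed_form_landmarks(self):
        assert alpha_kernel_value(0.0, 2.0, 0.7) == 0.0
        assert alpha_kernel_value(2.0, 2.0, 0.7) == pytest.approx(0.7)
        assert alpha_kernel_value(4.0, 2.0, 0.7) == pytest.approx(0.7 * 2 / math.e)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            alpha_kernel_value(-0.1, 2.0)

    @pytest.mark.parametrize("dt,tol", [(0.1, 0.02), (0.01, 0.002)])
    def test_filter_recurrence_matches_closed_form(self, dt, tol):
        """After a single presynaptic spike the engine's two-stage filter
        reproduces the alpha conductance within the stated bound over
        [0, 5 tau] (the exponential-integrator stages are exact at grid
        points, so the error is far inside the bound)."""
        tau, w = 2.0, 0.5
        # driver population spikes exactly once: huge refractory pacemaker
        pre = cbsim.NeuronParams(10.0, -50.0, -70.0, -70.0, 50.0, 1e6)
        post = cbsim.NeuronParams(10.0, -55.0, -70.0, -70.0, 0.0, 1.0)
        spec = cbsim.TileModelSpec(
            layers=[
                cbsim.LayerSpec("a", 50.0, [cbsim.SheetSpec("SRC", 1, 1)]),
                cbsim.LayerSpec("b", 50.0, [cbsim.SheetSpec("TGT", 1, 1)]),
            ],
            neuron_params={"SRC": pre, "TGT": post},
            projections=[
                cbsim.ProjectionSpec(
                    "SRC", "TGT",
                    cbsim.GaussianKernel(1.0, 1000.0),
                    [cbsim.ReceptorParams("AMPA", tau, w)],
                )
            ],
        )
        settings = cbsim.SimulationSettings(duration=100.0, dt=dt, seed=0)
        graph = cbsim.build_network(spec, settings)
        assert graph.n_synapses == 1
        sim = Simulator(graph, settings)
        g_hist = []
        spike_step = None
        for k in range(settings.n_steps):
            spikes = sim.step()
            if len(spikes["SRC"]) and spike_step is None:
                spike_step = k
            g_hist.append(sim.state.populations["TGT"].channels[0].g[0])
        g_hist = np.array(g_hist)
        assert spike_step is not None
        # spike at step k arrives at k+1; g sampled at end of each step
        t_since = (np.arange(spike_step + 1, settings.n_steps) - spike_step) * dt
        expected = alpha_kernel_value(t_since, tau, w)
        sel = t_since <= 5 * tau
        err = np.abs(g_hist[spike_step + 1 :][sel] - expected[sel])
        assert err.max() <= tol * w
        assert g_hist[spike_step] == 0.0  # one-step synaptic delay


# ---------------------------------------------------------------------------
# single-neuron membrane dynamics
# ---------------------------------------------------------------------------

class TestIsolatedNeurons:
    def test_rest_is_fixed_point(self):
        p = cbsim.NeuronParams(10.0, -55.0, -70.0, -70.0, 0.0, 1.0)
        graph, settings = isolated_population_graph("ST", p, duration=500)
        rec, _ = cbsim.run_simulation(graph, settings)
        assert rec.n_spikes() == 0
        sim = Simulator(graph, settings)
        sim.run(5000)
        assert np.all(sim.state.populations["ST"].v == -70.0)

    def test_subthreshold_drive_never_fires(self):
        p = cbsim.NeuronParams(10.0, -50.0, -70.0, -70.0, 19.9, 1.0)
        graph, settings = isolated_population_graph("X", p, duration=2000)
        rec, _ = cbsim.run_simulation(graph, settings)
        assert rec.n_spikes() == 0

    @pytest.mark.parametrize("pop", ["PC", "DCN", "IO", "pons"])
    def test_pacemaker_isi_matches_closed_form(self, base_spec, pop):
        """Every pacemaking published parameter row: simulated ISI within
        1% of t_ref + tau_m*ln(i_ex/(i_ex - (theta - e_rest)))."""
        p = base_spec.neuron_params[pop]
        duration = 20000.0 if pop == "IO" else 2000.0
        graph, settings = isolated_population_graph(pop, p, duration=duration)
        rec, _ = cbsim.run_simulation(graph, settings)
        t = rec.times(pop)[rec.idx[pop] == 0]
        assert len(t) >= 2
        isi = np.diff(t).mean()
        assert isi == pytest.approx(lif_isi(p), rel=0.01)

    def test_io_fires_below_one_hz(self, base_spec):
        # the 1.5 s refractory period caps the climbing-fiber rate
        assert 1000.0 / lif_isi(base_spec.neuron_params["IO"]) == pytest.approx(
            0.664, abs=0.01
        )


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

class TestPoissonDriver:
    @pytest.mark.parametrize("rate", [8.0, 50.0])
    def test_empirical_rate_within_3se(self, rate):
        p = cbsim.NeuronParams(10.0, -50.0, -70.0, -70.0, 0.0, 1.0)
        drv = cbsim.DriverSpec("pons", "poisson_rate", rate=rate)
        graph, settings = isolated_population_graph(
            "pons", p, n=32, duration=5000, drivers=[drv]
        )
        rec, _ = cbsim.run_simulation(graph, settings)
        n = rec.n_spikes("pons")
        expect = rate * 1024 * 5.0
        assert abs(n - expect) <= 3 * np.sqrt(expect)

    def test_zero_rate_silent(self):
        p = cbsim.NeuronParams(10.0, -50.0, -70.0, -70.0, 0.0, 1.0)
        drv = cbsim.DriverSpec("pons", "poisson_rate", rate=0.0)
        graph, settings = isolated_population_graph(
            "pons", p, n=8, duration=1000, drivers=[drv]
        )
        rec, _ = cbsim.run_simulation(graph, settings)
        assert rec.n_spikes() == 0

    def test_poisson_counts_are_poisson_dispersed(self):
        p = cbsim.NeuronParams(10.0, -50.0, -70.0, -70.0, 0.0, 1.0)
        drv = cbsim.DriverSpec("pons", "poisson_rate", rate=8.0)
        graph, settings = isolated_population_graph(
            "pons", p, n=32, duration=10000, drivers=[drv]
        )
        rec, _ = cbsim.run_simulation(graph, settings)
        counts = np.bincount(rec.idx["pons"], minlength=1024)
        # Fano factor of per-cell counts ~ 1 (refractoriness shaves ~0.1%)
        fano = counts.var(ddof=1) / counts.mean()
        assert 0.8 < fano < 1.2
        assert counts.mean() == pytest.approx(80.0, rel=0.05)


class TestSinusoidDriver:
    def test_drive_modulates_rate_with_stated_phase(self):
        # NRTP-like pacemaker under A(1 - cos)/2: silent at t=0, fastest
        # mid-cycle
        p = cbsim.NeuronParams(40.0, -60.0, -70.0, -70.0, 0.0, 1.0)
        drv = cbsim.DriverSpec(
            "NRTP", "sinusoid_current", amplitude=18.0, period=2000.0
        )
        graph, settings = isolated_population_graph(
            "NRTP", p, n=8, duration=2000, drivers=[drv]
        )
        rec, _ = cbsim.run_simulation(graph, settings)
        t = rec.times("NRTP")
        assert rec.n_spikes() > 0
        assert t.min() > 250.0  # silent near the trough
        first_half = np.count_nonzero((t > 500) & (t <= 1000))
        crest = np.count_nonzero((t > 750) & (t <= 1250))
        assert crest >= first_half


# ---------------------------------------------------------------------------
# run contracts
# ---------------------------------------------------------------------------

class TestRunContracts:
    def test_zero_steps_empty_record(self, small_graph):
        rec, _ = cbsim.run_simulation(small_graph, n_steps=0)
        assert rec.n_spikes() == 0

    def test_refractory_bounds_every_isi(self, small_spec):
        spec = cbsim.TileModelSpec.from_dict(small_spec.to_dict())
        for d in spec.drivers:
            d.rate = 50.0
        settings = cbsim.SimulationSettings(duration=500, seed=2)
        graph = cbsim.build_network(spec, settings)
        rec, _ = cbsim.run_simulation(graph, settings)
        assert rec.n_spikes() > 1000
        for pop in graph.populations:
            t_ref = spec.neuron_params[pop].t_ref
            t = rec.times(pop)
            idx = rec.idx[pop]
            order = np.lexsort((t, idx))
            t, idx = t[order], idx[order]
            same = idx[1:] == idx[:-1]
            if np.any(same):
                assert np.diff(t)[same].min() >= t_ref - 1e-9

    def test_seed_reproducibility(self, small_graph):
        a, _ = cbsim.run_simulation(small_graph, sim_seed=3, n_steps=3000)
        b, _ = cbsim.run_simulation(small_graph, sim_seed=3, n_steps=3000)
        c, _ = cbsim.run_simulation(small_graph, sim_seed=4, n_steps=3000)
        for pop in a.populations:
            assert np.array_equal(a.steps[pop], b.steps[pop])
            assert np.array_equal(a.idx[pop], b.idx[pop])
        assert any(
            not np.array_equal(a.steps[pop], c.steps[pop]) for pop in a.populations
        )

    def test_spike_tsv_format(self, small_graph, tmp_path):
        rec, _ = cbsim.run_simulation(small_graph, sim_seed=3, n_steps=2000)
        out = tmp_path / "spikes.tsv"
        rec.write_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "t_ms\tgid\tpopulation\tx_um\ty_um\tz_um"
        assert len(lines) == rec.n_spikes() + 1
        t_prev = 0.0
        for line in lines[1:50]:
            fields = line.split("\t")
            assert len(fields) == 6
            assert float(fields[0]) >= t_prev
            t_prev = float(fields[0])


# ---------------------------------------------------------------------------
# tile partitioning
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def quad_graph(small_spec):
    settings = cbsim.SimulationSettings(duration=500, tile_grid=(2, 2), seed=6)
    spec = cbsim.TileModelSpec.from_dict(small_spec.to_dict())
    for d in spec.drivers:
        d.rate = 50.0  # strong drive so halo spikes actually flow
    return cbsim.build_network(spec, settings)


class TestPartitionEquivalence:

    def test_partitioned_run_bit_identical_to_fused(self, quad_graph):
        """Stepping 2x2 tiles with halo exchange reproduces the fused
        single-partition run spike for spike."""
        a, _ = cbsim.run_simulation(quad_graph, sim_seed=1, partitioned=False)
        b, timing = cbsim.run_simulation(quad_graph, sim_seed=1, partitioned=True)
        assert a.n_spikes() > 1000
        for pop in a.populations:
            assert np.array_equal(a.steps[pop], b.steps[pop])
            assert np.array_equal(a.idx[pop], b.idx[pop])
        assert timing.communication_s.sum() > 0.0

    def test_halo_sources_cover_all_cross_tile_spikes(self, quad_graph):
        sim = Simulator(quad_graph, partitioned=True)
        for _ in range(1500):
            sim.step()
        inbox = sim.exchange_halo_spikes(0)
        halo = quad_graph.halo_map()
        for src, per_pop in inbox.items():
            allowed = set(halo[(src, 0)].tolist())
            for pop, loc in per_pop.items():
                grid = quad_graph.populations[pop]
                gids = grid.offset + src * grid.per_tile + loc
                assert set(gids.tolist()) <= allowed

    def test_single_tile_no_communication(self, small_graph):
        _, timing = cbsim.run_simulation(small_graph, sim_seed=1, partitioned=True, n_steps=500)
        assert timing.communication_s.sum() == 0.0


class TestInhibitionSanity:
    def test_stronger_golgi_inhibition_lowers_granule_rate(self, base_spec):
        """Monotone 3-point check on a reduced network with dense Golgi
        coverage (the feedback loop that shapes the granular reservoir)."""
        rates = []
        for w in (0.0, 1.0, 8.0):
            spec = cbsim.scale_tile_spec(base_spec, 0.04)
            for d in spec.drivers:
                d.rate = 50.0
            proj = spec.projection("GO", "GR")
            proj.kernel.p_peak = 0.5
            proj.receptors[0].weight = w
            settings = cbsim.SimulationSettings(duration=800, seed=3)
            graph = cbsim.build_network(spec, settings)
            rec, _ = cbsim.run_simulation(graph, settings)
            rates.append(cbsim.mean_firing_rate(rec, "GR", (200, 800)))
        assert rates[0] > rates[1] > rates[2]
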