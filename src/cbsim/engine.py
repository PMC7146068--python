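"""Forward-Euler dynamics of the conductance-based LIF network.

The membrane equation per neuron is

    tau_m dv/dt = -(v - e_rest) - sum_r g_r (v - e_rev_r) + i_ex + drive(t)

advanced by forward Euler at a fixed step (0.1 ms by default).  Each
receptor is an alpha-function conductance realized as the standard
two-stage linear filter,

    g <- d (g + (dt/tau) h),   h <- d h,   d = exp(-dt/tau),

an exact exponential-integrator update per stage whose response to an
impulse h += e*w reproduces the peak-normalized alpha kernel
w (t/tau) exp(1 - t/tau) at the grid points.  A spike emitted at step k
is delivered at step k+1 (one-step synaptic delay, also across tiles),
which is what makes tile-partitioned stepping with per-step neighbor
spike exchange bit-identical to stepping the whole array as one
partition.

Spiking: threshold test after the Euler update; v is reset and clamped
at v_reset for the absolute refractory period, during which the membrane
is not integrated (receptor filters keep evolving).  Populations under a
``poisson_rate`` driver bypass the membrane equation entirely and emit
independent Bernoulli(rate*dt) spikes (refractoriness still enforced).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .builder import NetworkGraph, PopulationGrid
from .config import SimulationSettings

_E = math.e


class NumericalError(RuntimeError):
    """Membrane state left the finite range (diverging simulation)."""


# ---------------------------------------------------------------------------
# alpha kernel (closed form; the filter's continuous-time limit)
# ---------------------------------------------------------------------------

def alpha_kernel_value(t_since_spike, tau_syn: float, weight: float = 1.0):
    """Peak-normalized alpha conductance w*(t/tau)*exp(1 - t/tau).

    Peaks at ``weight`` at ``t_since_spike == tau_syn``; zero at t = 0.
    """
    t = np.asarray(t_since_spike, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_spike must be >= 0")
    return weight * (t / tau_syn) * np.exp(1.0 - t / tau_syn)


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class ChannelState:
    """One receptor channel of a population; ``g``/``h`` are row views
    into the population's filter stacks."""

    kind: str
    tau_syn: float
    e_rev: float
    g: np.ndarray
    h: np.ndarray


@dataclass
class PopulationState:
    grid: PopulationGrid
    v: np.ndarray
    refrac: np.ndarray  # remaining refractory steps
    g_stack: np.ndarray  # (n_channels, n)
    h_stack: np.ndarray  # (n_channels, n)
    channels: list[ChannelState]
    spike_buf: np.ndarray
    poisson_rate: float | None = None  # Hz; replaces intrinsic dynamics


@dataclass
class StateVectors:
    populations: dict[str, PopulationState]

    def channel_index(self, pop: str, kind: str, tau_syn: float, e_rev: float) -> int:
        for i, c in enumerate(self.populations[pop].channels):
            if c.kind == kind and c.tau_syn == tau_syn and c.e_rev == e_rev:
                return i
        raise KeyError((pop, kind, tau_syn, e_rev))


def init_state(graph: NetworkGraph) -> StateVectors:
    """Fresh state: v at each population's resting potential, receptor
    filters and refractory clocks at zero."""
    # collect the distinct (kind, tau, e_rev) channels arriving at each
    # population, in spec projection order (deterministic)
    chan_keys: dict[str, list[tuple[str, float, float]]] = {
        name: [] for name in graph.populations
    }
    for pg in graph.projections:
        for r in pg.spec.receptors:
            key = (r.kind, r.tau_syn, r.e_rev)
            if key not in chan_keys[pg.post.name]:
                chan_keys[pg.post.name].append(key)
    pops: dict[str, PopulationState] = {}
    for name, grid in graph.populations.items():
        p = graph.spec.neuron_params[name]
        n = grid.n_total
        nc = len(chan_keys[name])
        g_stack = np.zeros((nc, n))
        h_stack = np.zeros((nc, n))
        channels = [
            ChannelState(kind, tau, e_rev, g_stack[i], h_stack[i])
            for i, (kind, tau, e_rev) in enumerate(chan_keys[name])
        ]
        pops[name] = PopulationState(
            grid=grid,
            v=np.full(n, p.e_rest, dtype=np.float64),
            refrac=np.zeros(n, dtype=np.int64),
            g_stack=g_stack,
            h_stack=h_stack,
            channels=channels,
            spike_buf=np.empty(n, dtype=np.int64),
        )
    for drv in graph.spec.drivers:
        if drv.mode == "poisson_rate":
            pops[drv.population].poisson_rate = drv.rate
    return StateVectors(pops)


# ---------------------------------------------------------------------------
# spike record / timing
# ---------------------------------------------------------------------------

@dataclass
class SpikeRecord:
    """All spikes of a run: per population, parallel (step, local index)
    arrays in time order.  Times are step*dt ms (a spike is recorded at
    the end of the step that crossed threshold)."""

    dt: float
    populations: dict[str, PopulationGrid]
    steps: dict[str, np.ndarray] = field(default_factory=dict)
    idx: dict[str, np.ndarray] = field(default_factory=dict)

    def times(self, pop: str) -> np.ndarray:
        return self.steps[pop] * self.dt

    def n_spikes(self, pop: str | None = None) -> int:
        if pop is not None:
            return len(self.steps[pop])
        return sum(len(s) for s in self.steps.values())

    def count_in_window(self, pop: str, t0: float, t1: float) -> int:
        t = self.times(pop)
        return int(np.count_nonzero((t >= t0) & (t < t1)))

    def write_tsv(self, path) -> None:
        """One row per event: t_ms, gid, population, x_um, y_um, z_um,
        sorted lexicographically by (t, gid)."""
        cols = []
        for pop, grid in self.populations.items():
            if pop not in self.steps or len(self.steps[pop]) == 0:
                continue
            t = self.times(pop)
            gid = grid.offset + self.idx[pop].astype(np.int64)
            x, y, z = grid.positions(self.idx[pop])
            cols.append((t, gid, np.full(len(t), pop, dtype=object), x, y, z))
        with open(path, "w") as fh:
            fh.write("t_ms\tgid\tpopulation\tx_um\ty_um\tz_um\n")
            if not cols:
                return
            t, gid, pop, x, y, z = (np.concatenate(c) for c in zip(*cols))
            for i in np.lexsort((gid, t)):
                fh.write(
                    f"{t[i]:.1f}\t{gid[i]}\t{pop[i]}\t{x[i]:.2f}\t{y[i]:.2f}\t{z[i]:.2f}\n"
                )


@dataclass
class TimingBreakdown:
    """Accumulated wall seconds per tile and compute phase."""

    n_tiles: int
    neuron_s: np.ndarray
    synapse_s: np.ndarray
    communication_s: np.ndarray
    total_s: float = 0.0

    @classmethod
    def zeros(cls, n_tiles: int) -> "TimingBreakdown":
        return cls(n_tiles, np.zeros(n_tiles), np.zeros(n_tiles), np.zeros(n_tiles))

    def as_dict(self) -> dict:
        return {
            "per_tile": [
                {
                    "tile": t,
                    "neuron_s": float(self.neuron_s[t]),
                    "synapse_s": float(self.synapse_s[t]),
                    "communication_s": float(self.communication_s[t]),
                }
                for t in range(self.n_tiles)
            ],
            "neuron_s": float(self.neuron_s.sum()),
            "synapse_s": float(self.synapse_s.sum()),
            "communication_s": float(self.communication_s.sum()),
            "total_s": float(self.total_s),
        }


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _step_membrane(
    v,
    refrac,
    g,
    h,
    decay,
    coef,
    e_rev,
    dt,
    tau_m,
    theta,
    v_reset,
    e_rest,
    i_drive,
    ref_steps,
    v_floor,
    spike_out,
):
    """Fused filter + Euler membrane update for one population slice.

    Writes slice-local spike indices into spike_out and returns their
    count.  Receptor filters evolve during refractoriness; the membrane
    does not (clamped at v_reset).  ``v_floor`` is the population's most
    negative reversal potential: forward Euler overshoots below it when
    the summed conductance exceeds 2*tau_m/dt, so v is clamped there —
    the physical fixed point of a strongly shunted membrane.
    """
    nc = g.shape[0]
    n = v.shape[0]
    count = 0
    a = dt / tau_m
    for i in range(n):
        syn = 0.0
        vi = v[i]
        for c in range(nc):
            gc = decay[c] * (g[c, i] + coef[c] * h[c, i])
            h[c, i] = decay[c] * h[c, i]
            g[c, i] = gc
            syn += gc * (vi - e_rev[c])
        if refrac[i] > 0:
            refrac[i] -= 1
            v[i] = v_reset
        else:
            vi = vi + a * (-(vi - e_rest) - syn + i_drive)
            if vi < v_floor:
                vi = v_floor
            if vi >= theta:
                spike_out[count] = i
                count += 1
                v[i] = v_reset
                refrac[i] = ref_steps
            else:
                v[i] = vi
    return count


def _gather_rows(indptr, data, rows):
    """Concatenate CSR rows (vectorized)."""
    cnt = indptr[rows + 1] - indptr[rows]
    total = int(cnt.sum())
    if total == 0:
        return data[:0]
    idx = np.repeat(indptr[rows] - np.cumsum(cnt) + cnt, cnt) + np.arange(total)
    return data[idx]


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------

class Simulator:
    """Steps a built network; owns state, drivers and spike recording.

    ``partitioned=True`` steps the tiles one at a time with explicit halo
    spike exchange and per-tile timing; ``False`` treats the whole array
    as a single partition.  The two paths are numerically identical by
    construction — synaptic impulses are accumulated per edge block as
    ``weight * e * integer_count`` and membrane updates are per-neuron
    independent — which the test suite verifies bit-exactly.
    """

    def __init__(
        self,
        graph: NetworkGraph,
        settings: SimulationSettings | None = None,
        sim_seed: int | None = None,
        partitioned: bool = False,
    ):
        self.graph = graph
        self.settings = settings or graph.settings
        self.dt = self.settings.dt
        self.partitioned = partitioned
        self.state = init_state(graph)
        seed = self.settings.seed if sim_seed is None else sim_seed
        self._rngs = {
            name: np.random.Generator(
                np.random.Philox(
                    np.random.SeedSequence(entropy=seed, spawn_key=(0x73696D, k))
                )
            )
            for k, name in enumerate(graph.populations)
        }
        self.timing = TimingBreakdown.zeros(graph.n_tiles)
        self._halo = graph.halo_map() if partitioned else {}
        self.step_index = 0
        # per-population spikes of the previous step (sorted local indices)
        self._prev: dict[str, np.ndarray] = {
            name: np.empty(0, dtype=np.int64) for name in graph.populations
        }
        self._rec_steps: dict[str, list] = {name: [] for name in graph.populations}
        self._rec_idx: dict[str, list] = {name: [] for name in graph.populations}
        self._deliveries = self._index_deliveries()
        self._drivers = list(graph.spec.drivers)
        # per-population constants for the membrane kernel
        self._consts = {}
        for name, st in self.state.populations.items():
            p = graph.spec.neuron_params[name]
            floor = min(
                [c.e_rev for c in st.channels] + [p.v_reset, p.e_rest]
            )
            self._consts[name] = (
                np.array([math.exp(-self.dt / c.tau_syn) for c in st.channels]),
                np.array([self.dt / c.tau_syn for c in st.channels]),
                np.array([c.e_rev for c in st.channels]),
                floor,
            )
        self._check_every = 1000

    def _index_deliveries(self):
        """Precompute (edge block -> post channel) delivery plans."""
        plans = []
        for pg in self.graph.projections:
            chans = [
                (
                    self.state.channel_index(pg.post.name, r.kind, r.tau_syn, r.e_rev),
                    _E * r.weight,
                )
                for r in pg.spec.receptors
            ]
            for (st_, pt), (indptr, posts) in sorted(pg.blocks.items()):
                plans.append(
                    {
                        "pre": pg.pre.name,
                        "post": pg.post.name,
                        "pre_tile": st_,
                        "post_tile": pt,
                        "indptr": indptr,
                        "posts": posts,
                        "chans": chans,
                        "n_post_tile": pg.post.per_tile,
                        "post_slice": slice(
                            pt * pg.post.per_tile, (pt + 1) * pg.post.per_tile
                        ),
                    }
                )
        return plans

    # -- drivers ------------------------------------------------------------

    def _current_drive(self, pop: str, t_ms: float) -> float:
        extra = 0.0
        for d in self._drivers:
            if d.population != pop:
                continue
            if d.mode == "constant_current":
                extra += d.amplitude
            elif d.mode == "sinusoid_current":
                extra += (
                    d.amplitude
                    * (1.0 - math.cos(2.0 * math.pi * t_ms / d.period + d.phase))
                    / 2.0
                )
        return extra

    # -- one step -----------------------------------------------------------

    def _deliver(self, plan, spikes_tile_local):
        """Accumulate one block's impulses for the given presynaptic spikes."""
        targets = _gather_rows(plan["indptr"], plan["posts"], spikes_tile_local)
        if len(targets) == 0:
            return
        counts = np.bincount(targets, minlength=plan["n_post_tile"]).astype(np.float64)
        sl = plan["post_slice"]
        chans = self.state.populations[plan["post"]].channels
        for ci, inc in plan["chans"]:
            chans[ci].h[sl] += inc * counts

    def _spikes_of_tile(self, pop: str, tile: int) -> np.ndarray:
        """Previous-step spikes of *pop* within *tile*, tile-local indices."""
        prev = self._prev[pop]
        per = self.graph.populations[pop].per_tile
        lo = np.searchsorted(prev, tile * per)
        hi = np.searchsorted(prev, (tile + 1) * per)
        return prev[lo:hi] - tile * per

    def exchange_halo_spikes(self, tile: int) -> dict[int, dict[str, np.ndarray]]:
        """Assemble the inbox of *tile*: previous-step spikes of halo
        sources in each neighboring tile (filtered against the halo map,
        returned as per-population tile-local indices)."""
        inbox: dict[int, dict[str, np.ndarray]] = {}
        for src in self.graph.tile_neighbors(tile):
            key = (src, tile)
            if key not in self._halo:
                continue
            halo_gids = self._halo[key]
            per_pop: dict[str, np.ndarray] = {}
            for pop, grid in self.graph.populations.items():
                loc = self._spikes_of_tile(pop, src)
                if len(loc) == 0:
                    continue
                gids = grid.offset + src * grid.per_tile + loc
                sent = loc[np.isin(gids, halo_gids, assume_unique=True)]
                if len(sent):
                    per_pop[pop] = sent
            inbox[src] = per_pop
        return inbox

    def step(self) -> dict[str, np.ndarray]:
        """Advance the network by one dt; returns this step's spikes
        (per-population sorted local indices)."""
        t_ms = self.step_index * self.dt
        new_spikes: dict[str, np.ndarray] = {}
        n_tiles = self.graph.n_tiles

        # 1) synaptic propagation: spikes emitted at t - dt arrive now
        if self.partitioned:
            for tile in range(n_tiles):
                if self._halo:
                    tc0 = time.perf_counter()
                    inbox = self.exchange_halo_spikes(tile)
                    tc1 = time.perf_counter()
                    self.timing.communication_s[tile] += tc1 - tc0
                else:
                    inbox = {}
                    tc1 = time.perf_counter()
                for plan in self._deliveries:
                    if plan["post_tile"] != tile:
                        continue
                    src = plan["pre_tile"]
                    if src == tile:
                        spikes = self._spikes_of_tile(plan["pre"], tile)
                    else:
                        spikes = inbox.get(src, {}).get(
                            plan["pre"], np.empty(0, dtype=np.int64)
                        )
                    if len(spikes):
                        self._deliver(plan, spikes)
                self.timing.synapse_s[tile] += time.perf_counter() - tc1
        else:
            for plan in self._deliveries:
                t0 = time.perf_counter()
                spikes = self._spikes_of_tile(plan["pre"], plan["pre_tile"])
                if len(spikes):
                    self._deliver(plan, spikes)
                self.timing.synapse_s[plan["post_tile"]] += time.perf_counter() - t0

        # 2) membrane / emission update, tile by tile
        for pop, st in self.state.populations.items():
            params = self.graph.spec.neuron_params[pop]
            grid = st.grid
            per = grid.per_tile
            ref_steps = int(round(params.t_ref / self.dt))
            if st.poisson_rate is not None:
                t0 = time.perf_counter()
                # dead-time-compensated emission probability: with the
                # refractory period enforced, Bernoulli(rate*dt) would
                # undershoot the nominal rate by rate*t_ref; solving
                # 1/(t_ref + dt/p) = rate gives the exact correction.
                rate_ms = st.poisson_rate * 1e-3
                if rate_ms > 0 and 1.0 / rate_ms > params.t_ref:
                    p = self.dt / (1.0 / rate_ms - params.t_ref)
                else:
                    p = st.poisson_rate * self.dt * 1e-3
                draw = self._rngs[pop].random(grid.n_total) < p
                draw &= st.refrac == 0
                fired = np.flatnonzero(draw)
                st.refrac[st.refrac > 0] -= 1
                st.refrac[fired] = ref_steps
                self.timing.neuron_s += (time.perf_counter() - t0) / n_tiles
                new_spikes[pop] = fired
                continue
            decay, coef, e_rev, v_floor = self._consts[pop]
            drive = params.i_ex + self._current_drive(pop, t_ms)
            fired_parts = []
            for tile in range(n_tiles):
                sl = slice(tile * per, (tile + 1) * per)
                t0 = time.perf_counter()
                count = _step_membrane(
                    st.v[sl],
                    st.refrac[sl],
                    st.g_stack[:, sl],
                    st.h_stack[:, sl],
                    decay,
                    coef,
                    e_rev,
                    self.dt,
                    params.tau_m,
                    params.theta,
                    params.v_reset,
                    params.e_rest,
                    drive,
                    ref_steps,
                    v_floor,
                    st.spike_buf[sl],
                )
                self.timing.neuron_s[tile] += time.perf_counter() - t0
                if count:
                    fired_parts.append(st.spike_buf[sl.start : sl.start + count] + tile * per)
            new_spikes[pop] = (
                np.concatenate(fired_parts) if fired_parts else np.empty(0, np.int64)
            )

        # 3) record and rotate
        for pop, fired in new_spikes.items():
            if len(fired):
                self._rec_steps[pop].append(
                    np.full(len(fired), self.step_index, dtype=np.int32)
                )
                self._rec_idx[pop].append(fired.astype(np.int32))
            self._prev[pop] = fired
        self.step_index += 1
        if self.step_index % self._check_every == 0:
            for pop, st in self.state.populations.items():
                if st.poisson_rate is None and not np.all(np.isfinite(st.v)):
                    raise NumericalError(
                        f"non-finite membrane potential in {pop} at t={t_ms} ms"
                    )
        return new_spikes

    def run(self, n_steps: int | None = None) -> tuple[SpikeRecord, TimingBreakdown]:
        wall0 = time.perf_counter()
        if n_steps is None:
            n_steps = self.settings.n_steps
        for _ in range(n_steps):
            self.step()
        self.timing.total_s += time.perf_counter() - wall0
        return self.record(), self.timing

    def record(self) -> SpikeRecord:
        rec = SpikeRecord(self.dt, dict(self.graph.populations))
        for pop in self.graph.populations:
            if self._rec_steps[pop]:
                rec.steps[pop] = np.concatenate(self._rec_steps[pop])
                rec.idx[pop] = np.concatenate(self._rec_idx[pop])
            else:
                rec.steps[pop] = np.empty(0, dtype=np.int32)
                rec.idx[pop] = np.empty(0, dtype=np.int32)
        return rec


def run_simulation(
    graph: NetworkGraph,
    settings: SimulationSettings | None = None,
    sim_seed: int | None = None,
    partitioned: bool = False,
    n_steps: int | None = None,
) -> tuple[SpikeRecord, TimingBreakdown]:
    """Build state, step ``n_steps`` (default settings.duration/dt), and
    return the spike record plus the timing breakdown."""
    sim = Simulator(graph, settings, sim_seed=sim_seed, partitioned=partitioned)
    return sim.run(n_steps)
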