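"""Turnkey benchmark protocols.

Three protocols probe the tile model:

resting state
    pons cells emit spontaneous 8 Hz Poisson spikes; after a warmup the
    per-population mean rates are summarized (the model's hallmark is
    the ordering PC > DCN > ST ~ BA > GR > GO).

strong constant input
    pons cells fire at 50 Hz; granule cells then show reservoir-like
    random alternation between burst and silent states, quantified by
    the similarity index of the granule population.

optokinetic response (OKR)
    the NRTP relay receives a non-negative sinusoidal current (period
    2 s, minimum at t = 0) and drives granule cells; Purkinje cells
    modulate out of phase with NRTP, and vestibular-nucleus cells out of
    phase with PCs (disinhibition).  Rate traces are summarized by
    cosine fits and modulation ranges.

A weak-scaling harness replicates a fixed per-tile load over growing
tile arrays (tiles stepped sequentially with per-step halo spike
exchange) and reports the neuron / synapse / communication time split
per tile.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import analysis
from .builder import NetworkGraph, build_network
from .config import (
    NRTP_DRIVE_AMPLITUDE,
    SimulationSettings,
    TileModelSpec,
    builtin_cerebellar_tile_spec,
    builtin_okr_extension_spec,
    scale_tile_spec,
)
from .engine import SpikeRecord, TimingBreakdown, run_simulation

DEFAULT_WARMUP = 500.0  # ms excluded from every analysis window


@dataclass
class ExperimentResult:
    """A protocol run: spikes, summaries, and enough metadata to re-run."""

    condition: str
    record: SpikeRecord
    timing: TimingBreakdown
    graph: NetworkGraph
    window: tuple[float, float]  # analysis window, ms
    mean_rates: dict[str, float]
    rate_traces: dict[str, analysis.RateTrace] = field(default_factory=dict)
    fits: dict[str, analysis.CosineFit] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


@dataclass
class OKRProtocol:
    """Sinusoidal NRTP drive: amplitude * (1 - cos(2 pi t/period))/2."""

    period: float = 2000.0  # ms
    amplitude: float = NRTP_DRIVE_AMPLITUDE
    cycles: int = 2

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.cycles < 1:
            raise ValueError("need at least one cycle")

    @property
    def freq_hz(self) -> float:
        return 1000.0 / self.period


def _prepare(
    spec: TileModelSpec,
    settings: SimulationSettings | None,
    density_factor: float,
    duration: float,
    seed: int,
    warmup: float,
) -> tuple[TileModelSpec, SimulationSettings]:
    if density_factor != 1.0:
        spec = scale_tile_spec(spec, density_factor)
    if settings is None:
        settings = SimulationSettings(duration=max(duration, 0.1), seed=seed, warmup=warmup)
    else:
        settings = dataclasses.replace(
            settings, duration=max(duration, 0.1), warmup=warmup
        )
    return spec, settings


def _set_poisson_rate(spec: TileModelSpec, population: str, rate: float) -> None:
    for d in spec.drivers:
        if d.population == population and d.mode == "poisson_rate":
            d.rate = rate
            return
    raise ValueError(f"no poisson driver on {population!r}")


def _run(
    spec: TileModelSpec,
    settings: SimulationSettings,
    condition: str,
    sim_seed: int | None,
    graph: NetworkGraph | None = None,
    partitioned: bool = False,
    n_steps: int | None = None,
) -> ExperimentResult:
    if graph is None:
        graph = build_network(spec, settings)
    record, timing = run_simulation(
        graph, settings, sim_seed=sim_seed, partitioned=partitioned, n_steps=n_steps
    )
    t1 = (n_steps if n_steps is not None else settings.n_steps) * settings.dt
    window = (min(settings.warmup, t1), t1)
    mean_rates = {}
    if window[1] > window[0]:
        mean_rates = {
            pop: analysis.mean_firing_rate(record, pop, window)
            for pop in graph.populations
        }
    return ExperimentResult(
        condition=condition,
        record=record,
        timing=timing,
        graph=graph,
        window=window,
        mean_rates=mean_rates,
        metadata={
            "seed": settings.seed,
            "sim_seed": sim_seed,
            "tile_grid": list(settings.tile_grid),
            "duration_ms": t1,
            "warmup_ms": settings.warmup,
        },
    )


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def run_resting_state(
    settings: SimulationSettings | None = None,
    density_factor: float = 1.0,
    seed: int = 0,
    duration: float = 2500.0,
    warmup: float = DEFAULT_WARMUP,
    sim_seed: int | None = None,
    graph: NetworkGraph | None = None,
) -> ExperimentResult:
    """Spontaneous condition: pons Poisson at 8 Hz.

    *duration* includes the *warmup*; mean rates are computed over
    [warmup, duration].  Pass a prebuilt *graph* to reuse wiring across
    simulation seeds.
    """
    spec = builtin_cerebellar_tile_spec()
    spec, settings = _prepare(spec, settings, density_factor, duration, seed, warmup)
    n_steps = 0 if duration == 0 else None
    return _run(spec, settings, "resting", sim_seed, graph=graph, n_steps=n_steps)


def run_strong_input(
    settings: SimulationSettings | None = None,
    density_factor: float = 1.0,
    seed: int = 0,
    duration: float = 2500.0,
    warmup: float = DEFAULT_WARMUP,
    rate: float = 50.0,
    sim_seed: int | None = None,
    graph: NetworkGraph | None = None,
) -> ExperimentResult:
    """Constant strong mossy-fiber input: pons Poisson at 50 Hz."""
    spec = builtin_cerebellar_tile_spec()
    _set_poisson_rate(spec, "pons", rate)
    spec, settings = _prepare(spec, settings, density_factor, duration, seed, warmup)
    n_steps = 0 if duration == 0 else None
    return _run(spec, settings, "strong_input", sim_seed, graph=graph, n_steps=n_steps)


def run_okr(
    settings: SimulationSettings | None = None,
    protocol: OKRProtocol | None = None,
    density_factor: float = 1.0,
    seed: int = 0,
    warmup: float = DEFAULT_WARMUP,
    bin_ms: float = analysis.DEFAULT_RATE_BIN,
    sim_seed: int | None = None,
    graph: NetworkGraph | None = None,
) -> ExperimentResult:
    """OKR protocol: sinusoidal NRTP drive over ``protocol.cycles`` full
    periods (after *warmup*); returns NRTP/PC/VN rate traces with cosine
    fits.  The inferior olive keeps its intrinsic slow pacemaking (no
    retinal-slip drive); VN receives only PC inhibition plus its
    constant i_ex."""
    protocol = protocol or OKRProtocol()
    spec = builtin_okr_extension_spec()
    for d in spec.drivers:
        if d.mode == "sinusoid_current" and d.population == "NRTP":
            d.amplitude = protocol.amplitude
            d.period = protocol.period
    duration = warmup + protocol.cycles * protocol.period
    spec, settings = _prepare(spec, settings, density_factor, duration, seed, warmup)
    result = _run(spec, settings, "okr", sim_seed, graph=graph)
    result.metadata["protocol"] = dataclasses.asdict(protocol)
    for pop in ("NRTP", "PC", "VN"):
        trace = analysis.rate_trace(result.record, pop, result.window, bin_ms)
        result.rate_traces[pop] = trace
        result.fits[pop] = analysis.cosine_fit(trace, protocol.freq_hz)
    return result


# ---------------------------------------------------------------------------
# weak-scaling harness
# ---------------------------------------------------------------------------

@dataclass
class ScalingReport:
    """Per tile-count timing rows from the weak-scaling harness."""

    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_scaling_benchmark(
    tile_counts,
    duration: float = 200.0,
    density_factor: float = 0.01,
    seed: int = 0,
    tile_size: float = 1000.0,
) -> ScalingReport:
    """Weak scaling at desk scale: a constant per-tile model is replicated
    over growing square-ish tile arrays and stepped for a fixed biological
    time with per-step halo spike exchange; wall time is split into
    neuron / synapse / communication components per tile.

    Tiles are stepped sequentially by one process, so constant *per-tile*
    neuron+synapse seconds across rows is the desk-scale analogue of flat
    total time on one-process-per-tile hardware.
    """
    report = ScalingReport()
    base = builtin_cerebellar_tile_spec()
    spec = scale_tile_spec(base, density_factor) if density_factor != 1.0 else base
    for n_tiles in tile_counts:
        gx = int(round(np.sqrt(n_tiles)))
        if gx * gx == n_tiles:
            grid = (gx, gx)
        else:
            grid = (int(n_tiles), 1)
        settings = SimulationSettings(
            duration=duration, tile_grid=grid, tile_size=tile_size, seed=seed
        )
        try:
            graph = build_network(spec, settings)
            _, timing = run_simulation(graph, settings, partitioned=True)
        except MemoryError:
            report.rows.append({"tiles": n_tiles, "failed": True})
            continue
        report.rows.append(
            {
                "tiles": n_tiles,
                "neurons": graph.n_neurons,
                "synapses": graph.n_synapses,
                "neuron_s": float(timing.neuron_s.sum()),
                "synapse_s": float(timing.synapse_s.sum()),
                "communication_s": float(timing.communication_s.sum()),
                "total_s": float(timing.total_s),
                "neuron_s_per_tile": float(timing.neuron_s.mean()),
                "synapse_s_per_tile": float(timing.synapse_s.mean()),
            }
        )
    return report
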