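"""Spike-pattern analysis: rates, exponential activity traces, the
population similarity index, and cosine fits of modulated firing rates.

The similarity index quantifies how gradually the active granule-cell
population changes under sustained input.  Each cell's spike train is
low-pass filtered into a trace

    z_i(t) = (1/tau) * sum_{s <= t} exp(-(t - s)/tau) f_i(s),

(f_i(s) = 1 iff cell i spiked in step s; tau defaults to 50 ms, the
Purkinje-cell EPSP decay), and SI(dt) is the cosine similarity between
the population vectors z(t) and z(t + dt), averaged over a window T
(default 2 s).  SI(0) = 1 by construction and 0 <= SI <= 1 since z >= 0;
a slow decay in dt means the active population turns over gradually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import SpikeRecord

DEFAULT_TAU_PC = 50.0  # ms
DEFAULT_SI_WINDOW = 2000.0  # ms
DEFAULT_SI_LAGS = np.arange(0.0, 501.0, 10.0)  # ms
DEFAULT_RATE_BIN = 50.0  # ms


# ---------------------------------------------------------------------------
# firing rates
# ---------------------------------------------------------------------------

def mean_firing_rate(record: SpikeRecord, population: str, window) -> float:
    """Population-mean rate (Hz) over [t0, t1) ms; silent cells count in
    the denominator."""
    t0, t1 = window
    if population not in record.populations:
        raise KeyError(f"unknown population {population!r}")
    if t1 <= t0:
        raise ValueError(f"empty window {window}")
    n_cells = record.populations[population].n_total
    n_spikes = record.count_in_window(population, t0, t1)
    return n_spikes / (n_cells * (t1 - t0) * 1e-3)


@dataclass
class RateTrace:
    """Binned population-mean firing rate."""

    population: str
    bin_edges: np.ndarray  # ms, len n_bins + 1
    rates: np.ndarray  # Hz, len n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def rate_trace(
    record: SpikeRecord,
    population: str,
    window,
    bin_ms: float = DEFAULT_RATE_BIN,
) -> RateTrace:
    """Population-mean rate in fixed bins over [t0, t1) ms."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"empty window {window}")
    edges = np.arange(t0, t1 + 0.5 * bin_ms, bin_ms)
    t = record.times(population)
    counts, _ = np.histogram(t, bins=edges)
    n_cells = record.populations[population].n_total
    rates = counts / (n_cells * bin_ms * 1e-3)
    return RateTrace(population, edges, rates)


# ---------------------------------------------------------------------------
# z traces and similarity index
# ---------------------------------------------------------------------------

@dataclass
class ZTraceMatrix:
    """Exponentially filtered spike traces z_i(t) on the simulation grid."""

    population: str
    neurons: np.ndarray  # within-population indices, len n
    t0: float  # ms; trace column k is at t0 + k*dt
    dt: float
    tau_pc: float
    z: np.ndarray  # (n, n_steps)


def compute_z_traces(
    record: SpikeRecord,
    population: str,
    neurons,
    window,
    tau_pc: float = DEFAULT_TAU_PC,
) -> ZTraceMatrix:
    """Per-step recurrence z <- z*exp(-dt/tau) + f(t)/tau over [t0, t1).

    Spikes before t0 (back to the record start) are folded in so the
    trace carries no startup transient at t0.
    """
    if tau_pc <= 0:
        raise ValueError("tau_pc must be positive")
    t0, t1 = window
    neurons = np.asarray(neurons)
    dt = record.dt
    k0 = int(round(t0 / dt))
    k1 = int(round(t1 / dt))
    n_steps = k1 - k0
    n = len(neurons)
    decay = np.exp(-dt / tau_pc)

    # map the sampled neurons' spikes onto (row, step)
    pos = {int(g): i for i, g in enumerate(neurons)}
    steps = record.steps[population]
    idx = record.idx[population]
    sel = np.isin(idx, neurons)
    steps, idx = steps[sel], idx[sel]
    rows = np.array([pos[int(g)] for g in idx], dtype=np.int64)

    z = np.zeros((n, n_steps))
    # warm-up: fold all spikes before k0 into the state one step before
    # the window (the loop's first decay then brings it to k0)
    warm = steps < k0
    z0 = np.zeros(n)
    if np.any(warm):
        w = (1.0 / tau_pc) * decay ** (k0 - 1 - steps[warm].astype(np.float64))
        np.add.at(z0, rows[warm], w)
    # in-window spikes, bucketed per step
    f = np.zeros((n, n_steps))
    inwin = (steps >= k0) & (steps < k1)
    np.add.at(f, (rows[inwin], steps[inwin].astype(np.int64) - k0), 1.0 / tau_pc)
    prev = z0
    for k in range(n_steps):
        prev = prev * decay + f[:, k]
        z[:, k] = prev
    return ZTraceMatrix(population, neurons, t0, dt, tau_pc, z)


@dataclass
class SimilarityCurve:
    """SI(dt) on a lag grid, with the per-lag count of excluded bins
    (time points where either population vector had zero norm)."""

    delta_ms: np.ndarray
    si: np.ndarray
    window_ms: float
    n_excluded: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def similarity_index(
    ztrace: ZTraceMatrix,
    delta_grid=DEFAULT_SI_LAGS,
    T: float = DEFAULT_SI_WINDOW,
) -> SimilarityCurve:
    """Time-averaged cosine similarity between population vectors z(t)
    and z(t + dt), for t over [t0, t0 + T).

    Bins where either vector has zero norm (e.g. before the first spike)
    are excluded from the average; if every bin of a lag is degenerate,
    an error is raised.
    """
    dt = ztrace.dt
    z = ztrace.z
    n_base = int(round(T / dt))
    delta_steps = np.array([int(round(d / dt)) for d in np.asarray(delta_grid)])
    if n_base + delta_steps.max() > z.shape[1]:
        raise ValueError(
            f"trace too short: need {(n_base + delta_steps.max()) * dt} ms, "
            f"have {z.shape[1] * dt} ms"
        )
    norms = np.sqrt(np.einsum("ik,ik->k", z, z))
    si = np.empty(len(delta_steps))
    excluded = np.empty(len(delta_steps), dtype=int)
    for j, ds in enumerate(delta_steps):
        num = np.einsum("ik,ik->k", z[:, :n_base], z[:, ds : ds + n_base])
        den = norms[:n_base] * norms[ds : ds + n_base]
        ok = den > 0
        excluded[j] = n_base - int(ok.sum())
        if not np.any(ok):
            raise ValueError(f"all {n_base} bins degenerate at lag {ds * dt} ms")
        si[j] = float(np.mean(num[ok] / den[ok]))
    return SimilarityCurve(np.asarray(delta_grid, dtype=float), si, T, excluded)


# ---------------------------------------------------------------------------
# cosine fits
# ---------------------------------------------------------------------------

@dataclass
class CosineFit:
    """Least-squares fit r(t) ~ a + b*cos(2*pi*f*t + phi), b >= 0."""

    offset: float  # a, Hz
    amplitude: float  # b, Hz (>= 0)
    phase: float  # phi, rad in (-pi, pi]
    freq: float  # f, Hz
    var_explained: float

    def as_dict(self) -> dict:
        return {
            "offset_hz": self.offset,
            "amplitude_hz": self.amplitude,
            "phase_rad": self.phase,
            "freq_hz": self.freq,
            "var_explained": self.var_explained,
        }


def cosine_fit(trace: RateTrace, f_hz: float) -> CosineFit:
    """Fit a + b*cos(2 pi f t + phi) by linear regression on the cosine
    and sine components (t in seconds; exact on noiseless cosines)."""
    if f_hz <= 0:
        raise ValueError("stimulus frequency must be positive")
    t_s = trace.bin_centers * 1e-3
    r = trace.rates
    if len(r) < 3:
        raise ValueError("need at least 3 bins to fit")
    span_s = (trace.bin_edges[-1] - trace.bin_edges[0]) * 1e-3
    if span_s * f_hz < 1.0 - 1e-9:
        raise ValueError("trace must span at least one stimulus cycle")
    w = 2.0 * np.pi * f_hz
    X = np.column_stack([np.ones_like(t_s), np.cos(w * t_s), np.sin(w * t_s)])
    beta, *_ = np.linalg.lstsq(X, r, rcond=None)
    a, bc, bs = beta
    b = float(np.hypot(bc, bs))
    phi = float(np.arctan2(-bs, bc)) if b > 0 else 0.0
    resid = r - X @ beta
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    ve = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return CosineFit(float(a), b, phi, f_hz, ve)


def modulation_range(fit: CosineFit) -> tuple[float, float]:
    """(a - b, a + b), floored at 0 Hz."""
    return (max(fit.offset - fit.amplitude, 0.0), fit.offset + fit.amplitude)


def phase_difference(fit_a: CosineFit, fit_b: CosineFit) -> float:
    """|phase difference| wrapped to [0, pi]."""
    d = (fit_a.phase - fit_b.phase) % (2.0 * np.pi)
    return float(min(d, 2.0 * np.pi - d))


# ---------------------------------------------------------------------------
# rasters and burst statistics
# ---------------------------------------------------------------------------

def sample_neurons(record: SpikeRecord, population: str, n: int, seed: int):
    """Deterministic random sample of within-population indices."""
    total = record.populations[population].n_total
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    return np.sort(rng.choice(total, size=min(n, total), replace=False))


def spike_raster_table(record: SpikeRecord, population: str, neurons, window):
    """Rows (t_ms, row_index) for a raster of the given neurons.

    ``row_index`` is the position of the neuron in *neurons* (0-based).
    """
    t0, t1 = window
    neurons = np.asarray(neurons)
    pos = {int(g): i for i, g in enumerate(neurons)}
    t = record.times(population)
    idx = record.idx[population]
    sel = (t >= t0) & (t < t1) & np.isin(idx, neurons)
    t, idx = t[sel], idx[sel]
    rows = np.array([pos[int(g)] for g in idx], dtype=np.int64)
    order = np.lexsort((rows, t))
    return np.column_stack([t[order], rows[order].astype(float)])


def burst_occupancy(
    record: SpikeRecord, population: str, neurons, window, bin_ms: float = 20.0
):
    """Per-cell fraction of bins with at least one spike.

    Cells alternating between burst and silent states have occupancy
    strictly between 0 and 1.
    """
    t0, t1 = window
    neurons = np.asarray(neurons)
    edges = np.arange(t0, t1 + 0.5 * bin_ms, bin_ms)
    n_bins = len(edges) - 1
    pos = {int(g): i for i, g in enumerate(neurons)}
    t = record.times(population)
    idx = record.idx[population]
    sel = (t >= t0) & (t < edges[-1]) & np.isin(idx, neurons)
    t, idx = t[sel], idx[sel]
    rows = np.array([pos[int(g)] for g in idx], dtype=np.int64)
    cols = np.minimum(((t - t0) / bin_ms).astype(np.int64), n_bins - 1)
    active = np.zeros((len(neurons), n_bins), dtype=bool)
    active[rows, cols] = True
    return active.mean(axis=1)
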