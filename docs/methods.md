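# Methods

`cbsim` simulates a layered-sheet model of the cerebellar microcircuit on
square tiles, at desk scale. This note records the model, the conventions
the printed parameter tables leave open, the numerical choices, and what
the reduced-density fixtures used in the test suite do and do not show.

## Neuron model

Every cell is a conductance-based leaky integrate-and-fire unit,

    tau_m dv/dt = -(v - E_rest) - sum_r g_r(t) (v - E_rev,r) + I_ex + I_drive(t)

advanced by forward Euler with a fixed step of dt = 0.1 ms. A spike is
emitted when the post-update v crosses theta (test after the update; the
spike time is the end of the step); v is then reset and clamped at
V_reset for the absolute refractory period t_ref, during which the
membrane is not integrated. Synaptic filters keep evolving during
refractoriness.

Units. Voltages are in mV, times in ms. Conductances are dimensionless,
relative to the leak conductance. `I_ex` is a constant depolarising
drive in mV at unit leak: the parameter tables give no input resistance,
so the printed "nA" values are only meaningful relative to leak. Under
this convention an isolated pacemaker has the closed-form period

    T = t_ref + tau_m * ln(I_ex / (I_ex - (theta - E_rest))),

which the engine reproduces within 1% at dt = 0.1 ms for every
pacemaking population (PC ~40 Hz intrinsic, DCN ~35 Hz, IO ~0.66 Hz with
its 1.5 s refractory period, pons ~53 Hz at I_ex 24). This is the main
evidence for the convention: with it, the Purkinje and deep-nucleus
resting rates land near their reference values once synaptic input is
added.

### Euler stability guard

Explicit Euler is unstable when the summed conductance exceeds
2*tau_m/dt (overshoot oscillation). For inhibitory input the oscillation
crosses below the GABA_A reversal and can spuriously *fire* the cell, so
after each update v is clamped at the population's most negative
reversal potential — the physical fixed point of a strongly shunted
membrane. The guard never engages in ordinary operation (it requires
hundreds of simultaneous inhibitory spikes on one cell) but makes the
scheme safe on reduced-density fixtures, where weight rescaling produces
very large unitary conductances.

## Synapses

Receptors are alpha-function conductances. A presynaptic spike at time s
contributes

    g(t) = w * ((t - s)/tau_syn) * exp(1 - (t - s)/tau_syn),

peak-normalized so the conductance peaks at the printed weight w at
tau_syn after delivery. The tables do not fix a normalization; peak
normalization makes the weights directly interpretable and is the only
reading under which the mossy-fiber EPSP on a granule cell (~10 mV
against a 23 mV gap) produces the coincidence-detection regime the model
is built around. The filter is implemented as the standard two coupled
first-order stages with exact exponential-integrator updates per stage
(`g <- d(g + (dt/tau) h)`, `h <- d h`, `d = exp(-dt/tau)`, impulse
`h += e*w`), which reproduces the alpha kernel exactly at the grid
points; the test suite bounds the error at <2% over [0, 5 tau].

All synapses have exactly one Euler step (0.1 ms) of delay, including
across tiles. Multiplicity is one: at most one synapse per (pre, post,
receptor). Transmitter follows the presynaptic type (GR, pons, NRTP, IO
excitatory; ST, BA, PC, GO inhibitory). Reversal potentials are not
printed; defaults are 0 mV (AMPA, NMDA) and -80 mV (GABA_A), exposed in
the config. NMDA is a slow (tau 100 ms) voltage-independent conductance;
GABA_B has no printed parameters and the config rejects it.

## Network geometry and wiring

A tile is 1 mm^2 and stacks, top to bottom: four 32x32 stellate sheets,
one 32x32 basket sheet, one 32x32 Purkinje sheet, eight 320x320 granule
sheets plus one 32x32 Golgi sheet, one 32x32 deep-nucleus sheet, a
single inferior-olive cell, and a 32x32 pons sheet (827,393 cerebellar
neurons + 1,024 pons cells per tile). Neuron ids are contiguous per
population and, within a population, per tile, so a tile's cells form
one slice of every state vector. x is mediolateral (parallel fibers run
along x), y rostrocaudal; kernels are planar (z is ignored).

Two kernel families wire the model. The radial Gaussian connects a pair
at planar distance d with probability `p_peak * exp(-d^2/(2 sigma^2))`,
cut off at 3 sigma (<1.2% of the mass). The orthogonal-cross kernel
connects, with uniform probability p, every postsynaptic cell inside an
axis-aligned rectangle centred on the presynaptic cell: mediolateral
half-extent `pre_width`, rostrocaudal full extent `post_width` — the
unique reading that reproduces every printed "projection area" row.
Each candidate pair is an independent Bernoulli draw; self-edges are
excluded.

Randomness is counter-based (Philox), one sub-stream per (projection,
presynaptic tile), consumed in a fixed order — so wiring is bit-stable
under any build chunking, and enlarging the tile array never rewires
existing tiles. At the array's outer boundary kernels are truncated
(open, the default) or wrapped with minimal-image distances (periodic;
used to emulate an interior tile in single-tile experiments). Under the
periodic convention each (pre, post) pair is considered once, at its
nearest image; kernel mass beyond half the array width is dropped.

The analytic out-degree `expected_degree` (2 pi sigma^2 p rho for the
Gaussian, cutoff-corrected; rectangle area x p x rho for the cross) is
exact in the continuum. On the discrete grids, sharp-edged rectangles
deviate from it by lattice commensuration (a few % at full density,
tens of % on coarse reduced grids); the wiring tests therefore compare
realized edge counts against the exact Bernoulli expectation enumerated
by brute force over all pairs.

## Tiles, halo exchange, partition equivalence

Edges are stored as per-(pre-tile, post-tile) CSR blocks. Cross-tile
blocks define the halo map: for each ordered tile pair, the presynaptic
cells whose spikes the neighbour must receive. In partitioned runs the
engine steps tiles sequentially; each tile first assembles its inbox
(previous-step spikes of its halo sources, timed as communication), then
accumulates synaptic impulses block by block, then updates membranes.
Impulses are accumulated as `weight * e * (integer spike count per
target)`, and membrane updates are per-neuron independent, so the
arithmetic is identical whether the array is stepped as one partition or
tile by tile — partition equivalence is exact by construction and
verified bit-for-bit in the tests. The one-step cross-tile delay equals
the ordinary synaptic delay, so no tile ever needs information newer
than one step.

The weak-scaling harness replicates a constant per-tile load over
growing arrays in a single process and reports neuron / synapse /
communication seconds per tile; constant per-tile compute time across
rows is the desk-scale analogue of flat wall time on
one-process-per-tile hardware. Per-step process pools are not used: at
0.1 ms steps the IPC would dominate every bucket.

## External drivers

`poisson_rate` replaces a population's intrinsic dynamics with
independent Bernoulli emission per step, with the refractory period
enforced and the emission probability dead-time compensated
(`p = dt/(1/rate - t_ref)`) so the delivered rate equals the nominal
rate. `constant_current` and `sinusoid_current` add to I_ex; the
sinusoid is `A (1 - cos(2 pi t/period + phase))/2` — non-negative, zero
at t = 0 for phase 0.

## Protocols

*Resting state*: pons cells emit 8 Hz Poisson spikes; rates are measured
over 2 s after a 500 ms warmup (the warmup lets pacemakers desynchronise
and slow NMDA filters charge). *Strong input*: pons at 50 Hz Poisson.
(A `constant_current` pacemaker alternative exists, but identical
deterministic pacemakers started from identical state stay in lockstep,
which is not a usable stand-in for an irregular 50 Hz afferent stream.)
*OKR*: the NRTP relay (tau_m 40 ms, theta -60 mV) receives the sinusoid
with period 2 s and amplitude A = 18, chosen once from the closed-form
pacemaker rate so NRTP peaks near 30 Hz; NRTP drives granule cells
through a Gaussian kernel (p 0.1, sigma 75 µm) with the mossy-fiber
weight 0.5; PC I_ex is 24 and the single IO keeps its intrinsic slow
pacemaking (no retinal-slip drive). The vestibular nucleus (a copy of
the DCN parameter row with I_ex 40, its own parameters being unprinted)
receives PC inhibition through a copy of the PC->DCN kernel; its weight
0.026 was calibrated once so the VN baseline sits near 35 Hz under
unmodulated Poisson PC input at the OKR-mean PC rate, and then frozen —
the modulation range is left as genuine validation. During OKR the pons
keeps its spontaneous 8 Hz drive (a 50 Hz setting would saturate the
granular layer).

Rate traces use 50 ms bins; modulated traces are fitted with
`a + b cos(2 pi f t + phi)` by linear regression on the cosine/sine
components (exact on noiseless cosines), and the modulation range is
`[a - b, a + b]` floored at zero.

## Granule-population similarity

Each granule spike train is filtered into
`z_i(t) = (1/tau_PC) sum_{s<=t} exp(-(t-s)/tau_PC) f_i(s)` (tau_PC =
50 ms) by the per-step recurrence `z <- z exp(-dt/tau) + f(t)/tau`,
which the tests verify against the direct sum to <1e-9. The similarity
index SI(dt) is the cosine similarity of the population vectors z(t) and
z(t+dt), averaged over a 2 s window; SI(0) = 1 and 0 <= SI <= 1 since z
is non-negative. Time bins where either vector has zero norm (before
the first spike) are excluded and counted. The default lag grid is
0–500 ms in 10 ms steps. Spikes earlier than the analysis window are
folded into the initial state so the trace carries no startup transient.

## Reduced-density fixtures

`scale_tile_spec` shrinks every sheet by sqrt(f) per axis and divides
the weights of projections whose presynaptic population shrank by the
realised density ratio, preserving expected in-degree x weight per
target. This keeps mean synaptic drive faithful but not its statistics:
unitary EPSPs grow as 1/f, in-degrees fall (at 4% density most granule
cells have no mossy input at all and the similarity index plateaus
high), and coarse grids break the lattice commensuration of the
full-density build. Reduced fixtures are therefore used for structural,
statistical and equivalence properties; the benchmark comparisons in
`tests/test_acceptance.py` and `scripts/acceptance.py` run the
full-density tile. Typical problem sizes: 4% density (~33k neurons) for
property tests, one full tile (~828k neurons, ~28M synapses, 2.5–4.5 s
of biological time) for the benchmarks.

## Known limitations

- Under the printed weights and the conventions above, the
  molecular-layer interneurons are fluctuation-driven with unitary
  granule EPSPs of ~0.03 mV against a 15 mV gap: they remain nearly
  silent in the resting condition, and granule cells sit in the
  triple-coincidence regime (~0.4 Hz) rather than the double-coincidence
  regime (~2 Hz). The resting benchmark reports whatever rates emerge;
  see the repository's acceptance outputs. Consequently Purkinje
  modulation during OKR follows its granule-cell excitation (in phase
  with the stimulus) rather than being inverted by ST/BA inhibition,
  and the VN modulation depth is shallower than its reference range
  even though its phase relation to PC (disinhibition) is correct.
- No synaptic plasticity (hence no OKR gain adaptation), no GABA_B, no
  NMDA voltage dependence, no conduction delays beyond the single Euler
  step, no sub-step spike interpolation.
- Periodic boundaries use minimal-image distances only; kernel mass
  beyond half the array width is dropped (relevant only when a kernel's
  cutoff exceeds half the array).
- Timing buckets are wall-clock measurements of a single-process run;
  they characterise scaling behaviour, not absolute hardware speed.
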