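# cbsim — desk-scale tile-partitioned cerebellar network simulation

`cbsim` is a spiking-network simulator for a layered-sheet model of the
cerebellar microcircuit, built for people who want to study — on a
single workstation — the network that large tile-parallel simulators run
on supercomputers: conductance-based leaky integrate-and-fire neurons
arranged in stacked 2-D sheets on square 1 mm² tiles, wired by radial
Gaussian kernels and rectangular parallel-fiber kernels, stepped by
forward Euler at 0.1 ms with per-step spike exchange between neighboring
tiles.

One tile holds 827,393 cerebellar neurons — stellate (ST), basket (BA),
Purkinje (PC), granule (GR, 819,200 of them), Golgi (GO), deep-nucleus
(DCN) cells and one inferior-olive (IO) cell — plus 1,024 pons cells
relaying mossy-fiber input; replicated over an 82,944-tile array the
model reaches the human cerebellum's 6.9 × 10¹⁰ neurons.

## Model

Each neuron integrates

    τ_m dv/dt = −(v − E_rest) − Σ_r g_r(t) (v − E_rev,r) + I_ex + I_drive(t)

with spike threshold θ, reset V_reset and absolute refractory period
t_ref. Each receptor (AMPA, NMDA, GABA_A) is an alpha-function
conductance `w (t/τ_syn) exp(1 − t/τ_syn)`, peak-normalized to the
synaptic weight. Connectivity is Bernoulli per cell pair under either
`p_peak exp(−d²/2σ²)` (radial) or a uniform-p rectangle (parallel
fibers). The granular layer's GR–GO loop turns sustained mossy input
into reservoir-like activity, quantified by the similarity index

    SI(Δt) = ⟨ z(t)·z(t+Δt) / (‖z(t)‖ ‖z(t+Δt)‖) ⟩_t ,
    z_i(t) = (1/τ_PC) Σ_{s≤t} e^{−(t−s)/τ_PC} f_i(s),

and the optokinetic-response (OKR) protocol drives the NRTP relay with a
sinusoidal current and reads out Purkinje and vestibular-nucleus (VN)
rate modulation by cosine fits. All default parameters (per-tile
counts, neuron constants, kernels, time constants, weights) are the
published values of the source model; `docs/methods.md` documents the
conventions, calibrations and known limitations.

## Worked example

A single reduced-density tile (4% neuron density, weights rescaled to
preserve per-target synaptic drive), resting condition — pons cells
firing 8 Hz Poisson spikes for 2.5 s:

```bash
$ cbsim run --experiment resting --density 0.04 --seed 7 --duration 2500 --out out/rest
   BA:   30.389 Hz
  DCN:   29.375 Hz
   GO:   22.542 Hz
   GR:    4.715 Hz
   IO:    0.500 Hz
   PC:   66.500 Hz
   ST:   31.562 Hz
 pons:    7.667 Hz
```

The numbers are population-mean rates over the 2 s after the 500 ms
warmup. The pacemakers behave as the closed form predicts (PC above its
~40 Hz intrinsic rate because of granule input, DCN pulled below its
~35 Hz intrinsic rate by Purkinje inhibition, IO at one spike per 1.5 s
refractory cycle, pons at the driven 8 Hz), while the
fluctuation-driven populations (ST, BA, GO, GR) are strongly
density-dependent: at 4% density the rescaled unitary EPSPs are 25×
larger, which makes the interneurons far more active than in the
full-density tile (see `docs/methods.md` on what reduced fixtures do
and do not show). The run directory contains `spikes.tsv` (one row per
spike: time, gid, population, position), `rates.csv` (50 ms binned
population rates) and `summary.json` (mean rates, timing breakdown,
and — for the OKR protocol — cosine fits and modulation ranges).

Other entry points: `cbsim run --experiment strong|okr`, `cbsim scale
--tiles 1,4,9` (weak-scaling timing rows per tile count), `cbsim spec
--builtin cerebellum|okr` (emit the default JSON specs), `cbsim analyze`
(rates / similarity / fits from a spike TSV), or the library functions
(`cbsim.run_resting_state`, `cbsim.run_okr`,
`cbsim.similarity_index`, ...).

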