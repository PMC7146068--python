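# File formats

Two JSON documents configure a run, and all outputs are plain text.
`cbsim spec --builtin cerebellum|okr --out file.json` emits complete,
valid examples of the network document.

## Simulation settings (JSON)

```json
{
  "duration": 2500,          // ms, required; positive multiple of dt
  "dt": 0.1,                 // ms, default 0.1
  "tile_grid": [1, 1],       // tiles along x and y, default [1, 1]
  "tile_size": 1000.0,       // µm, square tiles, default 1000
  "seed": 42,                // build + simulation seed, default 0
  "warmup": 500.0,           // ms excluded from analysis, default 0
  "output_dir": null,        // optional path
  "boundary": "open",        // "open" | "periodic"
  "n_workers": 1             // advisory (tiles are stepped sequentially)
}
```

Unknown keys are rejected; a missing `duration` is a configuration
error naming the key. Load with `parse_simulation_settings(path)`.

## Network model (JSON)

Four sections: `layers`, `neurons`, `projections`, `drivers`.

```json
{
  "layers": [
    {"name": "granular", "thickness": 200.0,
     "sheets": [{"population": "GR", "grid": [320, 320]},
                {"population": "GO", "grid": [32, 32]}]}
  ],
  "neurons": {
    "GR": {"tau_m": 7.2, "theta": -35, "v_reset": -70,
           "e_rest": -58, "i_ex": 0, "t_ref": 1}
  },
  "projections": [
    {"pre": "GO", "post": "GR",
     "kernel": {"type": "gaussian", "p_peak": 0.04, "sigma": 200.0,
                "cutoff_radius": 600.0},
     "receptors": [{"kind": "GABA_A", "tau_syn": 10.0, "weight": 3.0,
                    "e_rev": -80.0}]},
    {"pre": "GR", "post": "GO",
     "kernel": {"type": "orthogonal_cross", "pre_width": 250.0,
                "post_width": 100.0, "p": 0.025},
     "receptors": [{"kind": "AMPA", "tau_syn": 2.0, "weight": 0.0008},
                   {"kind": "NMDA", "tau_syn": 100.0, "weight": 0.00017}]}
  ],
  "drivers": [
    {"population": "pons", "mode": "poisson_rate", "rate": 8.0},
    {"population": "NRTP", "mode": "sinusoid_current",
     "amplitude": 18.0, "period": 2000.0, "phase": 0.0}
  ]
}
```

Notes: lengths in µm, times in ms, voltages in mV; a layer lists its
sheets top-down and a population may own several sheets (they must
share one grid shape); `cutoff_radius` defaults to 3 sigma; `e_rev`
defaults to 0 mV for AMPA/NMDA and -80 mV for GABA_A; receptor kinds
are limited to those three (GABA_B is rejected); driver modes are
`poisson_rate` (replaces intrinsic dynamics), `constant_current`, and
`sinusoid_current` (`amplitude*(1-cos(2*pi*t/period+phase))/2`, added
to i_ex). Load with `parse_network_spec(path)`; a validated spec
round-trips losslessly through `to_dict()`/`from_dict()`.

## Outputs

- `spikes.tsv` — one row per spike, sorted by (t, gid):
  `t_ms<TAB>gid<TAB>population<TAB>x_um<TAB>y_um<TAB>z_um`.
- `rates.csv` — binned population-mean rates: `t_ms,population,rate_hz`.
- `summary.json` — mean rates, run metadata, per-tile timing breakdown
  (`neuron_s`, `synapse_s`, `communication_s`, `total_s`), and for OKR
  runs the cosine fits and modulation ranges.
- `cbsim scale` CSV — one row per tile count: `tiles,neurons,synapses,
  neuron_s,synapse_s,communication_s,total_s,...` per-tile means.
- Optional adjacency dump (`write_edges_tsv`): `pre_gid,post_gid,
  receptor,weight` per synapse.
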