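"""Declarative model and simulation configuration.

Two JSON documents describe a run: *simulation settings* (duration, time
step, tile layout, seed) and a *network specification* (layers of neuron
sheets stacked on a tile, per-population neuron parameters, projections
with spatial kernels and receptors, and external drivers).  The builtin
specs returned by :func:`builtin_cerebellar_tile_spec` and
:func:`builtin_okr_extension_spec` encode the published cerebellar
microcircuit: one 1 mm^2 tile holds 827,393 cerebellar neurons (819,200
granule cells) plus 1,024 pons cells, wired by two-dimensional Gaussian
kernels and by rectangular parallel-fiber ("orthogonal cross") kernels.

Unit conventions
----------------
Times are in ms, lengths in µm, voltages in mV, rates in Hz.  Synaptic
weights are dimensionless peak conductances relative to the leak
conductance (a unit-weight spike peaks at relative conductance 1 at
t = tau_syn).  The constant external drive ``i_ex`` is interpreted as a
steady depolarisation in mV at unit leak conductance: the source tables
print "nA" but no input resistance, so the number is only meaningful
relative to the leak term, and this convention makes the printed values
directly comparable to (theta - e_rest).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

RECEPTOR_KINDS = ("AMPA", "NMDA", "GABA_A")
EXCITATORY_KINDS = ("AMPA", "NMDA")
BOUNDARY_MODES = ("open", "periodic")
DRIVER_MODES = ("poisson_rate", "constant_current", "sinusoid_current")

#: default reversal potentials (mV); not printed in the source tables,
#: standard values, overridable per receptor in the JSON dialect.
DEFAULT_E_REV = {"AMPA": 0.0, "NMDA": 0.0, "GABA_A": -80.0}


class ConfigError(ValueError):
    """A mandatory key is missing or a file is structurally unusable."""


class ValidationError(ValueError):
    """A parsed value violates a model invariant."""


@dataclass
class Violation:
    """One invariant violation found by :func:`validate_spec`."""

    path: str
    constraint: str
    value: object

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.constraint} (got {self.value!r})"


# ---------------------------------------------------------------------------
# simulation settings
# ---------------------------------------------------------------------------

@dataclass
class SimulationSettings:
    """Global run settings independent of the network model."""

    duration: float
    dt: float = 0.1
    tile_grid: tuple[int, int] = (1, 1)
    tile_size: float = 1000.0
    seed: int = 0
    warmup: float = 0.0
    output_dir: str | None = None
    boundary: str = "open"
    n_workers: int = 1

    def __post_init__(self) -> None:
        self.tile_grid = (int(self.tile_grid[0]), int(self.tile_grid[1]))
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if self.duration <= 0:
            raise ValidationError(f"duration must be positive, got {self.duration}")
        n_steps = self.duration / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9 * max(1.0, n_steps):
            raise ValidationError(
                f"duration {self.duration} is not a multiple of dt {self.dt}"
            )
        if self.tile_grid[0] < 1 or self.tile_grid[1] < 1:
            raise ValidationError(f"tile_grid components must be >= 1, got {self.tile_grid}")
        if self.tile_size <= 0:
            raise ValidationError(f"tile_size must be positive, got {self.tile_size}")
        if self.warmup < 0:
            raise ValidationError(f"warmup must be >= 0, got {self.warmup}")
        if self.boundary not in BOUNDARY_MODES:
            raise ValidationError(f"boundary must be one of {BOUNDARY_MODES}, got {self.boundary!r}")
        if self.n_workers < 1:
            raise ValidationError(f"n_workers must be >= 1, got {self.n_workers}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tile_grid"] = list(self.tile_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSettings":
        if "duration" not in d:
            raise ConfigError("missing mandatory key 'duration'")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown settings key(s): {sorted(unknown)}")
        kwargs = dict(d)
        if "tile_grid" in kwargs:
            tg = kwargs["tile_grid"]
            if not (isinstance(tg, (list, tuple)) and len(tg) == 2):
                raise ConfigError(f"tile_grid must be a pair, got {tg!r}")
            kwargs["tile_grid"] = (int(tg[0]), int(tg[1]))
        return cls(**kwargs)


def parse_simulation_settings(path: Union[str, Path]) -> SimulationSettings:
    """Read and validate a settings JSON file."""
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: not valid JSON: {exc}") from exc
    return SimulationSettings.from_dict(d)


# ---------------------------------------------------------------------------
# network model types
# ---------------------------------------------------------------------------

@dataclass
class NeuronParams:
    """Leaky integrate-and-fire parameters for one population.

    tau_m
        membrane time constant (ms).
    theta
        spike threshold (mV).
    v_reset
        post-spike reset potential (mV).
    e_rest
        resting (leak reversal) potential (mV).
    i_ex
        constant depolarising drive (mV at unit leak; see module docstring).
    t_ref
        absolute refractory period (ms).
    """

    tau_m: float
    theta: float
    v_reset: float
    e_rest: float
    i_ex: float = 0.0
    t_ref: float = 1.0


@dataclass
class ReceptorParams:
    """One synaptic receptor: an alpha-function conductance.

    ``weight`` scales the conductance so a single presynaptic spike peaks
    at relative conductance ``weight`` at ``tau_syn`` after delivery.
    """

    kind: str
    tau_syn: float
    weight: float
    e_rev: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in RECEPTOR_KINDS:
            raise ValidationError(
                f"unsupported receptor kind {self.kind!r}; supported: {RECEPTOR_KINDS}"
            )
        if self.e_rev is None:
            self.e_rev = DEFAULT_E_REV[self.kind]


@dataclass
class GaussianKernel:
    """Radial connection kernel: p(d) = p_peak * exp(-d^2 / (2 sigma^2)).

    Candidate pairs beyond ``cutoff_radius`` (default 3 sigma, <1.2% of the
    kernel mass) are never connected.
    """

    p_peak: float
    sigma: float
    cutoff_radius: float | None = None

    def __post_init__(self) -> None:
        if self.cutoff_radius is None:
            self.cutoff_radius = 3.0 * self.sigma

    def probability(self, d):
        import numpy as np

        p = self.p_peak * np.exp(-np.asarray(d, dtype=float) ** 2 / (2.0 * self.sigma**2))
        return np.where(np.asarray(d, dtype=float) <= self.cutoff_radius, p, 0.0)


@dataclass
class CrossKernel:
    """Rectangular parallel-fiber kernel.

    A presynaptic cell reaches every postsynaptic cell inside an
    axis-aligned rectangle centred on it: mediolateral (x) half-extent
    ``pre_width`` (full extent 2*pre_width), rostrocaudal (y) full extent
    ``post_width``; connection probability ``p`` uniformly inside.
    """

    pre_width: float
    post_width: float
    p: float

    @property
    def area_um2(self) -> float:
        return 2.0 * self.pre_width * self.post_width


Kernel = Union[GaussianKernel, CrossKernel]


@dataclass
class ProjectionSpec:
    pre: str
    post: str
    kernel: Kernel
    receptors: list[ReceptorParams]

    @property
    def name(self) -> str:
        return f"{self.pre}->{self.post}"


@dataclass
class SheetSpec:
    """One 2-D sheet of a population: nx x ny neurons per tile."""

    population: str
    nx: int
    ny: int


@dataclass
class LayerSpec:
    name: str
    thickness: float  # µm
    sheets: list[SheetSpec]


@dataclass
class DriverSpec:
    """External drive to one population.

    ``poisson_rate`` replaces the population's intrinsic dynamics with
    independent Bernoulli(rate*dt) emission (refractoriness enforced);
    ``constant_current`` / ``sinusoid_current`` add to the membrane
    equation's i_ex term.  The sinusoid is
    ``amplitude * (1 - cos(2 pi t / period + phase)) / 2`` — non-negative,
    minimum at t = 0 for phase 0.
    """

    population: str
    mode: str
    rate: float = 0.0
    amplitude: float = 0.0
    period: float = 1000.0
    phase: float = 0.0


@dataclass
class TileModelSpec:
    """Full declarative description of one tile's model."""

    layers: list[LayerSpec]
    neuron_params: dict[str, NeuronParams]
    projections: list[ProjectionSpec]
    drivers: list[DriverSpec] = field(default_factory=list)

    def populations(self) -> list[str]:
        seen: list[str] = []
        for layer in self.layers:
            for sheet in layer.sheets:
                if sheet.population not in seen:
                    seen.append(sheet.population)
        return seen

    def sheets_of(self, population: str) -> list[SheetSpec]:
        return [
            s for layer in self.layers for s in layer.sheets if s.population == population
        ]

    def count_per_tile(self, population: str) -> int:
        return sum(s.nx * s.ny for s in self.sheets_of(population))

    def total_per_tile(self) -> int:
        return sum(self.count_per_tile(p) for p in self.populations())

    def projection(self, pre: str, post: str) -> ProjectionSpec:
        for proj in self.projections:
            if proj.pre == pre and proj.post == post:
                return proj
        raise KeyError(f"no projection {pre}->{post}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def kernel_dict(k: Kernel) -> dict:
            if isinstance(k, GaussianKernel):
                return {
                    "type": "gaussian",
                    "p_peak": k.p_peak,
                    "sigma": k.sigma,
                    "cutoff_radius": k.cutoff_radius,
                }
            return {
                "type": "orthogonal_cross",
                "pre_width": k.pre_width,
                "post_width": k.post_width,
                "p": k.p,
            }

        return {
            "layers": [
                {
                    "name": layer.name,
                    "thickness": layer.thickness,
                    "sheets": [
                        {"population": s.population, "grid": [s.nx, s.ny]}
                        for s in layer.sheets
                    ],
                }
                for layer in self.layers
            ],
            "neurons": {
                name: dataclasses.asdict(p) for name, p in self.neuron_params.items()
            },
            "projections": [
                {
                    "pre": proj.pre,
                    "post": proj.post,
                    "kernel": kernel_dict(proj.kernel),
                    "receptors": [dataclasses.asdict(r) for r in proj.receptors],
                }
                for proj in self.projections
            ],
            "drivers": [dataclasses.asdict(d) for d in self.drivers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TileModelSpec":
        for key in ("layers", "neurons", "projections"):
            if key not in d:
                raise ConfigError(f"missing mandatory key {key!r}")
        layers = []
        for ld in d["layers"]:
            sheets = [
                SheetSpec(sd["population"], int(sd["grid"][0]), int(sd["grid"][1]))
                for sd in ld["sheets"]
            ]
            layers.append(LayerSpec(ld["name"], float(ld["thickness"]), sheets))
        neuron_params = {
            name: NeuronParams(**pd) for name, pd in d["neurons"].items()
        }
        projections = []
        for pd in d["projections"]:
            kd = dict(pd["kernel"])
            ktype = kd.pop("type")
            if ktype == "gaussian":
                kernel: Kernel = GaussianKernel(**kd)
            elif ktype == "orthogonal_cross":
                kernel = CrossKernel(**kd)
            else:
                raise ConfigError(f"unknown kernel type {ktype!r}")
            receptors = [ReceptorParams(**rd) for rd in pd["receptors"]]
            projections.append(
                ProjectionSpec(pd["pre"], pd["post"], kernel, receptors)
            )
        drivers = [DriverSpec(**dd) for dd in d.get("drivers", [])]
        spec = cls(layers, neuron_params, projections, drivers)
        violations = validate_spec(spec)
        if violations:
            raise ValidationError("; ".join(str(v) for v in violations))
        return spec


def parse_network_spec(path: Union[str, Path]) -> TileModelSpec:
    """Read and validate a network-model JSON file."""
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: not valid JSON: {exc}") from exc
    return TileModelSpec.from_dict(d)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_spec(spec: TileModelSpec) -> list[Violation]:
    """Collect every invariant violation in *spec* (empty list = valid)."""
    out: list[Violation] = []
    pops = set(spec.populations())

    for layer in spec.layers:
        if layer.thickness <= 0:
            out.append(Violation(f"layers[{layer.name}].thickness", "> 0", layer.thickness))
        for s in layer.sheets:
            if s.nx < 1 or s.ny < 1:
                out.append(
                    Violation(f"layers[{layer.name}].{s.population}.grid", ">= 1 per axis", (s.nx, s.ny))
                )

    thetas = [p.theta for p in spec.neuron_params.values()]
    rests = [p.e_rest for p in spec.neuron_params.values()]
    for name, p in spec.neuron_params.items():
        base = f"neurons[{name}]"
        if p.tau_m <= 0:
            out.append(Violation(f"{base}.tau_m", "> 0", p.tau_m))
        if not (p.v_reset <= p.e_rest < p.theta):
            out.append(
                Violation(base, "v_reset <= e_rest < theta", (p.v_reset, p.e_rest, p.theta))
            )
        if p.t_ref < 0:
            out.append(Violation(f"{base}.t_ref", ">= 0", p.t_ref))
    for name in pops - set(spec.neuron_params):
        out.append(Violation(f"neurons[{name}]", "population has neuron parameters", None))

    for i, proj in enumerate(spec.projections):
        base = f"projections[{i}:{proj.name}]"
        for end, nm in (("pre", proj.pre), ("post", proj.post)):
            if nm not in pops:
                out.append(Violation(f"{base}.{end}", "population declared in layers", nm))
        if not proj.receptors:
            out.append(Violation(f"{base}.receptors", "at least one receptor", 0))
        for j, r in enumerate(proj.receptors):
            rbase = f"{base}.receptors[{j}]"
            if r.tau_syn <= 0:
                out.append(Violation(f"{rbase}.tau_syn", "> 0", r.tau_syn))
            if r.weight < 0:
                out.append(Violation(f"{rbase}.weight", ">= 0", r.weight))
            if r.kind in EXCITATORY_KINDS:
                if thetas and not r.e_rev > max(thetas):
                    out.append(
                        Violation(f"{rbase}.e_rev", "excitatory e_rev > all thresholds", r.e_rev)
                    )
            elif rests and not r.e_rev <= min(rests):
                out.append(
                    Violation(f"{rbase}.e_rev", "inhibitory e_rev <= all resting potentials", r.e_rev)
                )
        k = proj.kernel
        if isinstance(k, GaussianKernel):
            if not (0 < k.p_peak <= 1):
                out.append(Violation(f"{base}.kernel.p_peak", "0 < p_peak <= 1", k.p_peak))
            if k.sigma <= 0:
                out.append(Violation(f"{base}.kernel.sigma", "> 0", k.sigma))
            elif k.cutoff_radius < 3.0 * k.sigma - 1e-9:
                out.append(
                    Violation(f"{base}.kernel.cutoff_radius", ">= 3*sigma", k.cutoff_radius)
                )
        else:
            if k.pre_width <= 0 or k.post_width <= 0:
                out.append(
                    Violation(f"{base}.kernel", "pre_width, post_width > 0", (k.pre_width, k.post_width))
                )
            if not (0 < k.p <= 1):
                out.append(Violation(f"{base}.kernel.p", "0 < p <= 1", k.p))

    for i, drv in enumerate(spec.drivers):
        base = f"drivers[{i}]"
        if drv.population not in pops:
            out.append(Violation(f"{base}.population", "population declared", drv.population))
        if drv.mode not in DRIVER_MODES:
            out.append(Violation(f"{base}.mode", f"one of {DRIVER_MODES}", drv.mode))
        if drv.rate < 0:
            out.append(Violation(f"{base}.rate", ">= 0", drv.rate))
        if drv.period <= 0:
            out.append(Violation(f"{base}.period", "> 0", drv.period))
    return out


# ---------------------------------------------------------------------------
# builtin specs (the published parameter tables)
# ---------------------------------------------------------------------------

def _transmitter(pre: str) -> str:
    """Transmitter by presynaptic type: granule/afferent cells are
    glutamatergic, all cortical interneurons and Purkinje cells GABAergic."""
    return "AMPA" if pre in ("GR", "pons", "NRTP", "IO") else "GABA_A"


#: calibration constant: PC->VN peak weight, chosen once so the baseline VN
#: mean rate sits near 35 Hz under unmodulated (Poisson, OKR-mean-rate)
#: Purkinje input through the realized wiring (see docs/methods.md).
PC_VN_WEIGHT = 0.026

#: calibration constant: peak of the sinusoidal NRTP drive (mV at unit
#: leak).  Closed-form pacemaker rate at the crest,
#: 1/(t_ref + tau_m*ln(A/(A-10))) with tau_m=40 ms, puts the NRTP peak
#: rate near 30 Hz for A = 18.
NRTP_DRIVE_AMPLITUDE = 18.0

#: resting mossy-fiber spontaneous rate (Hz), fed to pons cells as
#: independent Poisson emission.
PONS_RESTING_RATE = 8.0


def builtin_cerebellar_tile_spec() -> TileModelSpec:
    """The default one-tile cerebellar model (the published tables).

    Per-tile counts: ST 4,096 (4 sheets of 32x32), BA/PC/GO/DCN/pons 1,024
    (32x32), GR 819,200 (8 sheets of 320x320), IO 1.
    """
    layers = [
        LayerSpec("molecular_upper", 100.0, [SheetSpec("ST", 32, 32)] * 4),
        LayerSpec("molecular_lower", 100.0, [SheetSpec("BA", 32, 32)]),
        LayerSpec("purkinje", 30.0, [SheetSpec("PC", 32, 32)]),
        LayerSpec(
            "granular",
            200.0,
            [SheetSpec("GR", 320, 320)] * 8 + [SheetSpec("GO", 32, 32)],
        ),
        LayerSpec("dcn", 100.0, [SheetSpec("DCN", 32, 32)]),
        LayerSpec("io", 100.0, [SheetSpec("IO", 1, 1)]),
        LayerSpec("pons", 200.0, [SheetSpec("pons", 32, 32)]),
    ]
    neuron_params = {
        "ST": NeuronParams(10.0, -55.0, -70.0, -70.0, 0.0, 1.0),
        "BA": NeuronParams(10.0, -55.0, -70.0, -70.0, 0.0, 1.0),
        "PC": NeuronParams(10.0, -50.0, -70.0, -70.0, 22.0, 1.0),
        "GR": NeuronParams(7.2, -35.0, -70.0, -58.0, 0.0, 1.0),
        "GO": NeuronParams(12.0, -50.0, -70.0, -70.0, 0.0, 1.0),
        "DCN": NeuronParams(10.0, -40.0, -70.0, -70.0, 32.0, 1.0),
        "IO": NeuronParams(10.0, -50.0, -70.0, -70.0, 50.0, 1500.0),
        "pons": NeuronParams(10.0, -50.0, -70.0, -70.0, 24.0, 1.0),
    }

    def recs(pre: str, weight: float, tau: float = 2.0) -> list[ReceptorParams]:
        return [ReceptorParams(_transmitter(pre), tau, weight)]

    projections = [
        # radial Gaussian kernels
        ProjectionSpec("GO", "GR", GaussianKernel(0.04, 200.0), recs("GO", 3.0, tau=10.0)),
        ProjectionSpec("IO", "PC", GaussianKernel(1.0, 350.0), recs("IO", 0.1)),
        ProjectionSpec("pons", "GR", GaussianKernel(1.0, 25.0), recs("pons", 0.5)),
        # rectangular parallel-fiber / sagittal kernels
        ProjectionSpec("ST", "ST", CrossKernel(50.0, 200.0, 0.02), recs("ST", 0.02)),
        ProjectionSpec("ST", "PC", CrossKernel(50.0, 200.0, 0.1), recs("ST", 0.05)),
        ProjectionSpec("BA", "BA", CrossKernel(50.0, 200.0, 0.02), recs("BA", 0.02)),
        ProjectionSpec("BA", "PC", CrossKernel(50.0, 200.0, 0.1), recs("BA", 0.1)),
        ProjectionSpec("PC", "BA", CrossKernel(50.0, 200.0, 0.05), recs("PC", 0.01)),
        ProjectionSpec("PC", "DCN", CrossKernel(75.0, 600.0, 0.3), recs("PC", 0.0025)),
        ProjectionSpec("GR", "ST", CrossKernel(500.0, 100.0, 0.05), recs("GR", 0.00145)),
        ProjectionSpec("GR", "BA", CrossKernel(500.0, 100.0, 0.05), recs("GR", 0.00145)),
        ProjectionSpec("GR", "PC", CrossKernel(500.0, 100.0, 0.05), recs("GR", 0.0013)),
        ProjectionSpec(
            "GR",
            "GO",
            CrossKernel(250.0, 100.0, 0.025),
            [
                ReceptorParams("AMPA", 2.0, 0.0008),
                ReceptorParams("NMDA", 100.0, 0.00017),
            ],
        ),
    ]
    drivers = [DriverSpec("pons", "poisson_rate", rate=PONS_RESTING_RATE)]
    return TileModelSpec(layers, neuron_params, projections, drivers)


def builtin_okr_extension_spec() -> TileModelSpec:
    """The optokinetic-response extension of the base tile.

    Adds the NRTP mossy-fiber relay (32x32 cells, tau_m 40 ms, theta
    -60 mV, reset/rest -70 mV, t_ref 1 ms) projecting to granule cells
    with a Gaussian kernel (p_peak 0.1, sigma 75 µm), and the vestibular
    nucleus (32x32 cells, i_ex 40) inhibited by Purkinje cells.  PC i_ex
    is raised to 24.  NRTP carries a sinusoidal current drive (period
    2 s, minimum at t = 0).
    """
    spec = builtin_cerebellar_tile_spec()
    spec.layers.append(LayerSpec("nrtp", 200.0, [SheetSpec("NRTP", 32, 32)]))
    spec.layers.append(LayerSpec("vn", 100.0, [SheetSpec("VN", 32, 32)]))
    spec.neuron_params["NRTP"] = NeuronParams(40.0, -60.0, -70.0, -70.0, 0.0, 1.0)
    # VN parameters are not separately published; it shares the DCN row
    # (the other pacemaking cerebellar-output population) with i_ex 40.
    spec.neuron_params["VN"] = NeuronParams(10.0, -40.0, -70.0, -70.0, 40.0, 1.0)
    spec.neuron_params["PC"] = dataclasses.replace(spec.neuron_params["PC"], i_ex=24.0)
    spec.projections.append(
        ProjectionSpec(
            "NRTP",
            "GR",
            GaussianKernel(0.1, 75.0),
            [ReceptorParams("AMPA", 2.0, 0.5)],
        )
    )
    # PC->VN mirrors the published PC->DCN kernel; the weight is a
    # calibration constant (see docs/methods.md).
    spec.projections.append(
        ProjectionSpec(
            "PC",
            "VN",
            CrossKernel(75.0, 600.0, 0.3),
            [ReceptorParams("GABA_A", 2.0, PC_VN_WEIGHT)],
        )
    )
    spec.drivers.append(
        DriverSpec(
            "NRTP",
            "sinusoid_current",
            amplitude=NRTP_DRIVE_AMPLITUDE,
            period=2000.0,
            phase=0.0,
        )
    )
    return spec


# ---------------------------------------------------------------------------
# density scaling (reduced fixtures)
# ---------------------------------------------------------------------------

def scale_tile_spec(spec: TileModelSpec, density_factor: float) -> TileModelSpec:
    """Return a copy of *spec* with per-sheet neuron counts scaled down.

    Grid counts are scaled by sqrt(density_factor) per axis (rounded,
    minimum 1).  Synaptic weights of projections whose presynaptic
    population was actually scaled are divided by the realised density
    ratio, so the expected summed synaptic drive per postsynaptic neuron
    is preserved.  Drivers are unchanged.
    """
    if not (0 < density_factor <= 1):
        raise ValueError(f"density_factor must be in (0, 1], got {density_factor}")
    axis = math.sqrt(density_factor)
    ratios: dict[str, float] = {}
    layers = []
    for layer in spec.layers:
        sheets = []
        for s in layer.sheets:
            nx = max(1, round(s.nx * axis))
            ny = max(1, round(s.ny * axis))
            sheets.append(SheetSpec(s.population, nx, ny))
        layers.append(LayerSpec(layer.name, layer.thickness, sheets))
    scaled = TileModelSpec(
        layers,
        dict(spec.neuron_params),
        [],
        [dataclasses.replace(d) for d in spec.drivers],
    )
    for pop in spec.populations():
        old = spec.count_per_tile(pop)
        new = scaled.count_per_tile(pop)
        ratios[pop] = new / old
    for proj in spec.projections:
        factor = 1.0 / ratios[proj.pre]
        receptors = [
            dataclasses.replace(r, weight=r.weight * factor) for r in proj.receptors
        ]
        scaled.projections.append(
            ProjectionSpec(proj.pre, proj.post, dataclasses.replace(proj.kernel), receptors)
        )
    return scaled
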