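"""Network realization: neuron placement and kernel-based wiring.

Neurons live on regular per-sheet grids inside square tiles.  Global ids
are contiguous per population and, within a population, contiguous per
tile — ``gid = offset + tile*per_tile + sheet*nx*ny + iy*nx + ix`` — so a
tile's neurons of one population form one contiguous slice of the state
vectors.  Because every tile carries identical sheet grids, the union of
a population over the whole tile array is itself a single regular grid,
which the wiring code exploits: for each presynaptic cell the candidate
postsynaptic cells are a rectangular index window of that global grid.

Projections are realized edge-by-edge with independent Bernoulli draws
(at most one synapse per (pre, post, receptor); no self-edges), using one
counter-based random sub-stream per (projection, presynaptic tile), so
enlarging the tile array never perturbs the wiring of existing tiles.
Edges are stored in per-(pre-tile, post-tile) CSR blocks; blocks with
``pre tile != post tile`` define the halo map used for neighbor spike
exchange.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import (
    CrossKernel,
    GaussianKernel,
    ProjectionSpec,
    SimulationSettings,
    TileModelSpec,
    validate_spec,
)

#: candidate draws per vectorized chunk (build-time memory / speed knob;
#: does not affect the realized wiring, see _draw_chunked)
_CHUNK_DRAWS = 4_000_000


# ---------------------------------------------------------------------------
# population geometry
# ---------------------------------------------------------------------------

@dataclass
class PopulationGrid:
    """Placement of one population over the tile array.

    All sheets of a population must share one per-tile grid shape; the
    population then forms ``n_sheets`` stacked copies of a single global
    ``(tiles_x*nx) x (tiles_y*ny)`` grid.
    """

    name: str
    n_sheets: int
    nx: int  # per-tile grid, x (mediolateral)
    ny: int  # per-tile grid, y (rostrocaudal)
    tiles_x: int
    tiles_y: int
    tile_size: float
    z_sheets: np.ndarray  # (n_sheets,) depth of each sheet, µm
    offset: int = 0  # first global id of this population

    @property
    def spacing_x(self) -> float:
        return self.tile_size / self.nx

    @property
    def spacing_y(self) -> float:
        return self.tile_size / self.ny

    @property
    def per_tile(self) -> int:
        return self.n_sheets * self.nx * self.ny

    @property
    def n_tiles(self) -> int:
        return self.tiles_x * self.tiles_y

    @property
    def n_total(self) -> int:
        return self.per_tile * self.n_tiles

    @property
    def gx_total(self) -> int:
        return self.tiles_x * self.nx

    @property
    def gy_total(self) -> int:
        return self.tiles_y * self.ny

    def local_index(self, tile: int, sheet, iy, ix):
        """Within-population index from tile, sheet and within-tile grid coords."""
        return tile * self.per_tile + (sheet * self.ny + iy) * self.nx + ix

    def from_global_grid(self, sheet, gx, gy):
        """Within-population index from sheet and *global* grid coords."""
        tx = gx // self.nx
        ty = gy // self.ny
        tile = ty * self.tiles_x + tx
        return self.local_index(tile, sheet, gy - ty * self.ny, gx - tx * self.nx)

    def decompose(self, idx):
        """Inverse of :meth:`local_index`: (tile, sheet, iy, ix)."""
        tile, rest = np.divmod(idx, self.per_tile)
        sheet, rest = np.divmod(rest, self.nx * self.ny)
        iy, ix = np.divmod(rest, self.nx)
        return tile, sheet, iy, ix

    def positions(self, idx=None):
        """(x, y, z) in µm for the given within-population indices."""
        if idx is None:
            idx = np.arange(self.n_total)
        tile, sheet, iy, ix = self.decompose(np.asarray(idx))
        ty, tx = np.divmod(tile, self.tiles_x)
        x = tx * self.tile_size + (ix + 0.5) * self.spacing_x
        y = ty * self.tile_size + (iy + 0.5) * self.spacing_y
        z = self.z_sheets[sheet]
        return x, y, z

    def tile_of(self, idx):
        return np.asarray(idx) // self.per_tile


def place_populations(
    spec: TileModelSpec, settings: SimulationSettings
) -> dict[str, PopulationGrid]:
    """Lay every population out on its per-sheet grids over the tile array.

    Deterministic function of (spec, settings); sheet depths follow the
    declared layer stacking order (z grows with depth).
    """
    tx, ty = settings.tile_grid
    sheet_shapes: dict[str, tuple[int, int]] = {}
    z_lists: dict[str, list[float]] = {}
    z_top = 0.0
    for layer in spec.layers:
        dz = layer.thickness / max(1, len(layer.sheets))
        for k, sheet in enumerate(layer.sheets):
            shape = (sheet.nx, sheet.ny)
            prev = sheet_shapes.setdefault(sheet.population, shape)
            if prev != shape:
                raise ValueError(
                    f"population {sheet.population!r} has sheets of differing "
                    f"grid shapes {prev} and {shape}; not supported"
                )
            z_lists.setdefault(sheet.population, []).append(z_top + (k + 0.5) * dz)
        z_top += layer.thickness
    grids: dict[str, PopulationGrid] = {}
    offset = 0
    for pop in spec.populations():
        nx, ny = sheet_shapes[pop]
        g = PopulationGrid(
            name=pop,
            n_sheets=len(z_lists[pop]),
            nx=nx,
            ny=ny,
            tiles_x=tx,
            tiles_y=ty,
            tile_size=settings.tile_size,
            z_sheets=np.array(z_lists[pop]),
            offset=offset,
        )
        offset += g.n_total
        grids[pop] = g
    return grids


# ---------------------------------------------------------------------------
# analytic degree oracle
# ---------------------------------------------------------------------------

def expected_degree(kernel, density: float) -> float:
    """Expected synapse count per interior cell under *kernel*.

    *density* is in neurons per µm² (sheets included).  Passing the
    postsynaptic density gives the expected out-degree of an interior
    presynaptic cell; passing the presynaptic density gives the expected
    in-degree.  Open-boundary interior cells, cutoff-corrected.
    """
    if isinstance(kernel, GaussianKernel):
        s2 = kernel.sigma**2
        mass = 2.0 * math.pi * s2 * kernel.p_peak
        mass *= 1.0 - math.exp(-(kernel.cutoff_radius**2) / (2.0 * s2))
        return mass * density
    if isinstance(kernel, CrossKernel):
        return kernel.area_um2 * kernel.p * density
    raise TypeError(f"unknown kernel type {type(kernel)!r}")


# ---------------------------------------------------------------------------
# projection realization
# ---------------------------------------------------------------------------

@dataclass
class ProjectionGraph:
    """Realized edges of one projection, in per-tile-pair CSR blocks.

    ``blocks[(pre_tile, post_tile)]`` maps each presynaptic cell of
    ``pre_tile`` (within-tile local index) to its postsynaptic targets in
    ``post_tile`` (within-tile local index): ``indptr`` of length
    ``pre.per_tile + 1`` and a flat ``posts`` array.
    """

    spec: ProjectionSpec
    pre: PopulationGrid
    post: PopulationGrid
    blocks: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def n_edges(self) -> int:
        return sum(len(posts) for _, posts in self.blocks.values())

    def iter_edges(self):
        """Yield (pre_idx, post_idx) arrays (within-population indices)."""
        for (st, pt), (indptr, posts) in sorted(self.blocks.items()):
            pre_local = np.repeat(np.arange(self.pre.per_tile), np.diff(indptr))
            yield st * self.pre.per_tile + pre_local, pt * self.post.per_tile + posts


def _axis_window(x_pre, half_extent, spacing, n_total, periodic):
    """Index window [j0, j0+width) of global-grid columns within reach.

    Returns (j0 per pre, width).  For periodic boundaries the window is
    clipped to the grid size so each post cell appears at most once
    (minimal-image convention).
    """
    width = int(math.floor(2.0 * half_extent / spacing)) + 2
    if periodic:
        width = min(width, n_total)
        j0 = np.rint(x_pre / spacing - 0.5).astype(np.int64) - width // 2
    else:
        j0 = np.ceil((x_pre - half_extent) / spacing - 0.5).astype(np.int64)
    return j0, width


def _realize_tile(proj, pre, post, pre_tile, rng, periodic, chunk_draws=_CHUNK_DRAWS):
    """Bernoulli-realize all edges of *proj* whose presynaptic cell lies in
    *pre_tile*.  Returns (pre_local, post_global_local) index arrays.

    The random stream is consumed in a fixed order (presynaptic cells in
    local-index order, candidates in (sheet, y, x) order), so the result
    is independent of the chunking.
    """
    kernel = proj.kernel
    n_pre_tile = pre.per_tile
    # global grid coordinates of the tile's pre cells, in local-index order
    ty, tx = divmod(pre_tile, pre.tiles_x)
    sheet, iy, ix = pre.decompose(np.arange(n_pre_tile))[1:]
    gx = tx * pre.nx + ix
    gy = ty * pre.ny + iy
    x = (gx + 0.5) * pre.spacing_x
    y = (gy + 0.5) * pre.spacing_y

    if isinstance(kernel, GaussianKernel):
        half_x = half_y = kernel.cutoff_radius
    else:
        half_x, half_y = kernel.pre_width, kernel.post_width / 2.0
    jx0, wx = _axis_window(x, half_x, post.spacing_x, post.gx_total, periodic)
    jy0, wy = _axis_window(y, half_y, post.spacing_y, post.gy_total, periodic)
    n_sheets = post.n_sheets
    lx = post.gx_total * post.spacing_x
    ly = post.gy_total * post.spacing_y

    per_pre = n_sheets * wy * wx
    chunk = max(1, chunk_draws // per_pre)
    same_pop = pre.name == post.name
    out_pre: list[np.ndarray] = []
    out_post: list[np.ndarray] = []
    for lo in range(0, n_pre_tile, chunk):
        hi = min(lo + chunk, n_pre_tile)
        n = hi - lo
        jx = jx0[lo:hi, None] + np.arange(wx)[None, :]  # (n, wx)
        jy = jy0[lo:hi, None] + np.arange(wy)[None, :]  # (n, wy)
        dx = (jx + 0.5) * post.spacing_x - x[lo:hi, None]
        dy = (jy + 0.5) * post.spacing_y - y[lo:hi, None]
        if periodic:
            jx_idx = np.mod(jx, post.gx_total)
            jy_idx = np.mod(jy, post.gy_total)
            dx = dx - lx * np.rint(dx / lx)
            dy = dy - ly * np.rint(dy / ly)
            ok_x = np.abs(dx) <= half_x
            ok_y = np.abs(dy) <= half_y
        else:
            ok_x = (jx >= 0) & (jx < post.gx_total) & (np.abs(dx) <= half_x)
            ok_y = (jy >= 0) & (jy < post.gy_total) & (np.abs(dy) <= half_y)
            jx_idx = np.clip(jx, 0, post.gx_total - 1)
            jy_idx = np.clip(jy, 0, post.gy_total - 1)
        if isinstance(kernel, GaussianKernel):
            d2 = dx[:, None, :] ** 2 + dy[:, :, None] ** 2  # (n, wy, wx)
            p = kernel.p_peak * np.exp(-d2 / (2.0 * kernel.sigma**2))
            p[d2 > kernel.cutoff_radius**2] = 0.0
        else:
            p = np.full((n, wy, wx), kernel.p)
        p = p * (ok_x[:, None, :] & ok_y[:, :, None])
        # one independent draw per candidate, fixed consumption order
        hit = rng.random((n, n_sheets, wy, wx)) < p[:, None, :, :]
        pre_i, s, yi, xi = np.nonzero(hit)
        if len(pre_i) == 0:
            continue
        post_local = post.from_global_grid(
            s, jx_idx[pre_i, xi], jy_idx[pre_i, yi]
        )
        pre_local = (pre_i + lo).astype(np.int64)
        if same_pop:
            keep = pre_tile * pre.per_tile + pre_local != post_local
            pre_local, post_local = pre_local[keep], post_local[keep]
        out_pre.append(pre_local.astype(np.int32))
        out_post.append(post_local.astype(np.int32))
    if out_pre:
        return np.concatenate(out_pre), np.concatenate(out_post)
    return np.empty(0, np.int32), np.empty(0, np.int32)


def _edges_to_blocks(pre_local, post_local, pre, post):
    """Split edge arrays (sorted by pre_local) into per-post-tile CSR blocks."""
    blocks = {}
    post_tile = post_local // post.per_tile
    for pt in np.unique(post_tile):
        sel = post_tile == pt
        pl = pre_local[sel]
        posts = (post_local[sel] - pt * post.per_tile).astype(np.int32)
        indptr = np.zeros(pre.per_tile + 1, dtype=np.int64)
        np.cumsum(np.bincount(pl, minlength=pre.per_tile), out=indptr[1:])
        blocks[int(pt)] = (indptr, posts)
    return blocks


def connect_gaussian2d(pre, post, kernel, rng, periodic=False) -> ProjectionGraph:
    """Realize a radial-Gaussian projection (single RNG stream, all tiles)."""
    proj = ProjectionSpec(pre.name, post.name, kernel, [])
    return _realize_projection(proj, pre, post, rng, periodic)


def connect_orthogonal_cross(pre, post, kernel, rng, periodic=False) -> ProjectionGraph:
    """Realize a rectangular parallel-fiber projection."""
    proj = ProjectionSpec(pre.name, post.name, kernel, [])
    return _realize_projection(proj, pre, post, rng, periodic)


def _realize_projection(proj, pre, post, rng, periodic) -> ProjectionGraph:
    graph = ProjectionGraph(proj, pre, post)
    for pre_tile in range(pre.n_tiles):
        tile_rng = rng(pre_tile) if callable(rng) else rng
        pre_local, post_local = _realize_tile(
            proj, pre, post, pre_tile, tile_rng, periodic
        )
        for pt, block in _edges_to_blocks(pre_local, post_local, pre, post).items():
            graph.blocks[(pre_tile, pt)] = block
    return graph


# ---------------------------------------------------------------------------
# whole-network build
# ---------------------------------------------------------------------------

@dataclass
class NetworkGraph:
    spec: TileModelSpec
    settings: SimulationSettings
    populations: dict[str, PopulationGrid]
    projections: list[ProjectionGraph]

    @property
    def n_tiles(self) -> int:
        return self.settings.tile_grid[0] * self.settings.tile_grid[1]

    @property
    def n_neurons(self) -> int:
        return sum(g.n_total for g in self.populations.values())

    @property
    def n_synapses(self) -> int:
        return sum(p.n_edges for p in self.projections)

    def synapse_counts(self) -> dict[str, int]:
        return {p.name: p.n_edges for p in self.projections}

    def tile_neighbors(self, tile: int) -> list[int]:
        """The 8-neighborhood of *tile* (wrapped if the boundary is periodic)."""
        tx_n, ty_n = self.settings.tile_grid
        ty, tx = divmod(tile, tx_n)
        out = []
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dx == 0 and dy == 0:
                    continue
                nx, ny = tx + dx, ty + dy
                if self.settings.boundary == "periodic":
                    nx, ny = nx % tx_n, ny % ty_n
                elif not (0 <= nx < tx_n and 0 <= ny < ty_n):
                    continue
                t = ny * tx_n + nx
                if t != tile and t not in out:
                    out.append(t)
        return sorted(out)

    def halo_map(self) -> dict[tuple[int, int], np.ndarray]:
        """For each ordered tile pair (src, dst), the sorted global ids of
        src-tile cells whose spikes dst needs (cross-tile presynaptic
        sources, scanned from the realized edge blocks)."""
        out: dict[tuple[int, int], set] = {}
        for pg in self.projections:
            for (st, pt), (indptr, posts) in pg.blocks.items():
                if st == pt:
                    continue
                pre_local = np.flatnonzero(np.diff(indptr) > 0)
                gids = pg.pre.offset + st * pg.pre.per_tile + pre_local
                out.setdefault((st, pt), set()).update(gids.tolist())
        return {
            key: np.array(sorted(vals), dtype=np.int64) for key, vals in out.items()
        }


def build_network(spec: TileModelSpec, settings: SimulationSettings) -> NetworkGraph:
    """Realize the full network: placement plus every projection.

    Wiring uses one Philox (counter-based) sub-stream per (projection,
    presynaptic tile), keyed by the build seed, so the result is a
    deterministic function of (spec, settings) and unaffected by worker
    count or chunking.
    """
    violations = validate_spec(spec)
    if violations:
        raise ValueError(
            "invalid spec: " + "; ".join(str(v) for v in violations)
        )
    grids = place_populations(spec, settings)
    periodic = settings.boundary == "periodic"
    projections = []
    for k, proj in enumerate(spec.projections):
        pre, post = grids[proj.pre], grids[proj.post]

        def stream(pre_tile, _k=k):
            seq = np.random.SeedSequence(
                entropy=settings.seed, spawn_key=(0x6E657477, _k, pre_tile)
            )
            return np.random.Generator(np.random.Philox(seq))

        projections.append(_realize_projection(proj, pre, post, stream, periodic))
    return NetworkGraph(spec, settings, grids, projections)


def write_edges_tsv(graph: NetworkGraph, path, projection: str) -> None:
    """Dump one projection's edges as TSV (pre_gid, post_gid, receptor, weight)."""
    pg = next(p for p in graph.projections if p.name == projection)
    with open(path, "w") as fh:
        fh.write("pre_gid\tpost_gid\treceptor\tweight\n")
        for pre_idx, post_idx in pg.iter_edges():
            for r in pg.spec.receptors:
                for a, b in zip(pre_idx + pg.pre.offset, post_idx + pg.post.offset):
                    fh.write(f"{a}\t{b}\t{r.kind}\t{r.weight}\n")
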