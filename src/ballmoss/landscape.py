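"""Tree-stand landscapes on a fine patch raster.

The habitat is a rectangular landscape discretised into square patches of
0.1 m side (0.01 m^2), carrying a set of trees. Each tree has a trunk
(radius from DBH) and a circular crown; epiphytes establish only on crown
patches. The module derives per-patch fields (crown layer count, shading,
cover class), builds random or user-supplied stands, and advances stand
dynamics: diameter growth, density-dependent self-thinning, natural
regeneration, and abrupt anthropogenic density changes (deforestation /
reforestation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PATCH_SIZE = 0.1  # metres; 0.01 m^2 patches

#: cover-class codes for raster export
COVER_OPEN, COVER_CROWN, COVER_TRUNK = 0, 1, 2

#: default per-layer light interception of one crown
DEFAULT_SHADING_PER_LAYER = 0.5

#: crown radius (m) per cm of DBH; 15 cm DBH -> 1.5 m crown radius
CROWN_PER_DBH = 0.1
#: tree height (m) per cm of DBH
HEIGHT_PER_DBH = 0.35

#: mean stem diameter growth, cm per year
DBH_GROWTH_CM_YR = 0.13

#: Yoda self-thinning: mean mass proxy w = MASS_COEF * dbh^3 obeys
#: w_max = YODA_K * N^(-3/2) with N in trees/ha. YODA_K is tuned so that
#: unmanaged stands of mature (~30 cm DBH) trees equilibrate near
#: 180 trees/ha under growth + regeneration, the convergence density of
#: recovering dry-forest stands.
MASS_COEF = 0.5
YODA_K = MASS_COEF * 31.0**3 * 180.0**1.5

#: regeneration stops when open ground drops below this fraction
MIN_OPEN_FRACTION = 0.2

#: DBH of a newly recruited / planted sapling, cm
SAPLING_DBH = 1.0


class PlacementError(RuntimeError):
    """Raised when trees cannot be placed without trunk overlap."""


@dataclass
class Tree:
    """A single tree: position (m), stem diameter (cm) and crown geometry."""

    id: int
    x: float
    y: float
    dbh: float
    height: float
    crown_radius: float
    alive: bool = True

    @property
    def trunk_radius(self) -> float:
        return self.dbh / 200.0  # cm diameter -> m radius

    def __post_init__(self) -> None:
        if self.dbh <= 0:
            raise ValueError(f"tree {self.id}: dbh must be positive")
        if self.crown_radius < self.trunk_radius:
            raise ValueError(f"tree {self.id}: crown_radius < trunk radius")


@dataclass
class DensityChangeEvent:
    """An abrupt anthropogenic change in tree density.

    ``deforest`` removes `magnitude` (a fraction in [0, 1]) of the live
    trees; ``reforest`` adds `magnitude` saplings per hectare on open
    ground.
    """

    mode: str  # {"deforest", "reforest"}
    magnitude: float
    at_year: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("deforest", "reforest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "deforest" and not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("deforest magnitude must be a fraction in [0, 1]")
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")


@dataclass
class LandscapeGrid:
    """A rectangular landscape of 0.01 m^2 patches with scattered trees.

    Derived per-patch fields (all shaped (nx, ny), 0-based, half-open
    patches, patch index = floor(coordinate / 0.1)):

    ``n_layers``
        number of crowns covering the patch.
    ``host``
        id of the tallest tree whose crown covers the patch (-1 if open).
    ``trunk``
        True where a trunk stands.
    """

    extent: tuple[float, float]
    trees: list[Tree] = field(default_factory=list)
    patch_size: float = PATCH_SIZE
    shading_per_layer: float = DEFAULT_SHADING_PER_LAYER

    def __post_init__(self) -> None:
        self.nx = int(round(self.extent[0] / self.patch_size))
        self.ny = int(round(self.extent[1] / self.patch_size))
        for t in self.trees:
            if not (0 <= t.x <= self.extent[0] and 0 <= t.y <= self.extent[1]):
                raise ValueError(f"tree {t.id} outside landscape extent")
        self._next_id = 1 + max((t.id for t in self.trees), default=-1)
        self.rebuild_fields()

    # ------------------------------------------------------------------
    # derived fields
    # ------------------------------------------------------------------
    def rebuild_fields(self) -> None:
        """Recompute n_layers / host / trunk rasters from the tree list."""
        nx, ny = self.nx, self.ny
        self.n_layers = np.zeros((nx, ny), dtype=np.int16)
        self.host = np.full((nx, ny), -1, dtype=np.int32)
        self.trunk = np.zeros((nx, ny), dtype=bool)
        host_height = np.full((nx, ny), -np.inf)
        ps = self.patch_size
        for t in self.trees:
            if not t.alive:
                continue
            for radius, is_crown in ((t.crown_radius, True), (t.trunk_radius, False)):
                i0 = max(int((t.x - radius) / ps), 0)
                i1 = min(int((t.x + radius) / ps) + 1, nx)
                j0 = max(int((t.y - radius) / ps), 0)
                j1 = min(int((t.y + radius) / ps) + 1, ny)
                if i0 >= i1 or j0 >= j1:
                    continue
                # patch centres
                cx = (np.arange(i0, i1) + 0.5) * ps
                cy = (np.arange(j0, j1) + 0.5) * ps
                d2 = (cx[:, None] - t.x) ** 2 + (cy[None, :] - t.y) ** 2
                inside = d2 <= radius**2
                if is_crown:
                    self.n_layers[i0:i1, j0:j1] += inside
                    take = inside & (t.height > host_height[i0:i1, j0:j1])
                    self.host[i0:i1, j0:j1][take] = t.id
                    host_height[i0:i1, j0:j1][take] = t.height
                else:
                    self.trunk[i0:i1, j0:j1] |= inside

    @property
    def n_patches(self) -> int:
        return self.nx * self.ny

    @property
    def area_ha(self) -> float:
        return self.extent[0] * self.extent[1] / 10_000.0

    def live_trees(self) -> list[Tree]:
        return [t for t in self.trees if t.alive]

    def n_live_trees(self) -> int:
        return sum(t.alive for t in self.trees)

    def density_per_ha(self) -> float:
        return self.n_live_trees() / self.area_ha

    def tree_by_id(self, tid: int) -> Tree:
        for t in self.trees:
            if t.id == tid:
                return t
        raise KeyError(tid)

    def add_tree(self, x, y, dbh, height=None, crown_radius=None) -> Tree:
        if height is None:
            height = HEIGHT_PER_DBH * dbh
        if crown_radius is None:
            crown_radius = max(CROWN_PER_DBH * dbh, dbh / 200.0)
        t = Tree(self._next_id, float(x), float(y), float(dbh), float(height),
                 float(crown_radius))
        self._next_id += 1
        self.trees.append(t)
        return t

    # ------------------------------------------------------------------
    # shading and cover
    # ------------------------------------------------------------------
    def shading(self, exclude_host: bool = False) -> np.ndarray:
        """Per-patch shading fraction, 1 - (1-s1)^k for k crown layers.

        With ``exclude_host=True`` one layer (an epiphyte's own host crown)
        is discounted wherever at least one crown is present — the shading
        experienced at an attachment site.
        """
        k = self.n_layers.astype(float)
        if exclude_host:
            k = np.maximum(k - 1.0, 0.0)
        return 1.0 - (1.0 - self.shading_per_layer) ** k

    def shading_at(self, patch: tuple[int, int], exclude_tree: int | None = None) -> float:
        """Shading at one patch, optionally discounting one tree's crown."""
        i, j = patch
        if not (0 <= i < self.nx and 0 <= j < self.ny):
            raise IndexError("patch outside grid")
        k = int(self.n_layers[i, j])
        if exclude_tree is not None and k > 0:
            t = self.tree_by_id(exclude_tree)
            cx, cy = (i + 0.5) * self.patch_size, (j + 0.5) * self.patch_size
            if (cx - t.x) ** 2 + (cy - t.y) ** 2 <= t.crown_radius**2:
                k -= 1
        return 1.0 - (1.0 - self.shading_per_layer) ** k

    def cover_class(self) -> np.ndarray:
        cov = np.zeros((self.nx, self.ny), dtype=np.int8)
        cov[self.n_layers > 0] = COVER_CROWN
        cov[self.trunk] = COVER_TRUNK
        return cov

    def ground_cover(self) -> float:
        """Fraction of patches covered by crowns or trunks (0 = bare stand)."""
        covered = (self.n_layers > 0) | self.trunk
        return float(covered.mean())

    def open_fraction(self) -> float:
        return 1.0 - self.ground_cover()

    # ------------------------------------------------------------------
    # IO
    # ------------------------------------------------------------------
    def layout_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"id": t.id, "x_m": t.x, "y_m": t.y, "dbh_cm": t.dbh, "height_m": t.height}
                for t in self.trees
                if t.alive
            ]
        )

    def to_layout_csv(self, path) -> None:
        self.layout_frame().to_csv(path, index=False)

    def raster_frame(self) -> pd.DataFrame:
        """Grid snapshot as tidy raster (patch_x, patch_y, cover_class, shading)."""
        ii, jj = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        return pd.DataFrame(
            {
                "patch_x": ii.ravel(),
                "patch_y": jj.ravel(),
                "cover_class": self.cover_class().ravel(),
                "shading": self.shading().ravel(),
            }
        )


# ----------------------------------------------------------------------
# builders
# ----------------------------------------------------------------------
def _square_extent(area_ha: float) -> tuple[float, float]:
    side = math.sqrt(area_ha * 10_000.0)
    return (side, side)


def _place_uniform(n, extent, trunk_radius, rng, existing=(), max_tries=200):
    """Uniform random positions without trunk overlap (bounded retries)."""
    pts = [np.array([t.x, t.y]) for t in existing]
    radii = [t.trunk_radius for t in existing]
    out = []
    for _ in range(n):
        for _try in range(max_tries):
            p = rng.uniform([0, 0], extent)
            ok = all(
                np.hypot(*(p - q)) > trunk_radius + r for q, r in zip(pts, radii)
            )
            if ok:
                pts.append(p)
                radii.append(trunk_radius)
                out.append(p)
                break
        else:
            raise PlacementError(
                f"could not place {n} trees without trunk overlap "
                f"(placed {len(out)})"
            )
    return out


def build_static_landscape(
    area_ha: float,
    n_trees: int,
    crown_radius: float = 1.5,
    height_range: tuple[float, float] = (4.0, 8.0),
    dbh: float = 15.0,
    rng: np.random.Generator | None = None,
) -> LandscapeGrid:
    """Random stand: `n_trees` uniformly placed trees with identical crowns
    and random heights, on a square landscape of `area_ha` hectares."""
    if n_trees < 0:
        raise ValueError("n_trees must be >= 0")
    rng = np.random.default_rng(rng)
    extent = _square_extent(area_ha)
    grid = LandscapeGrid(extent, [])
    pts = _place_uniform(n_trees, extent, trunk_radius=dbh / 200.0, rng=rng)
    for k, p in enumerate(pts):
        h = rng.uniform(*height_range)
        grid.trees.append(Tree(k, p[0], p[1], dbh, h, crown_radius))
    grid._next_id = n_trees
    grid.rebuild_fields()
    return grid


def build_layout(
    tree_coords: pd.DataFrame | str,
    extent: tuple[float, float] | None = None,
    crown_radius: float | None = None,
) -> LandscapeGrid:
    """Landscape from an explicit tree table.

    `tree_coords` is a DataFrame (or CSV path) with columns
    id,x_m,y_m,dbh_cm,height_m. Crown radii follow the DBH allometry unless
    `crown_radius` fixes them.
    """
    if isinstance(tree_coords, (str, bytes)) or hasattr(tree_coords, "__fspath__"):
        tree_coords = pd.read_csv(tree_coords)
    required = {"id", "x_m", "y_m", "dbh_cm", "height_m"}
    if not required.issubset(tree_coords.columns):
        raise ValueError(f"layout table needs columns {sorted(required)}")
    if tree_coords.duplicated(subset=["x_m", "y_m"]).any():
        raise ValueError("duplicate tree coordinates in layout")
    if extent is None:
        side = float(max(tree_coords.x_m.max(), tree_coords.y_m.max()))
        # round up to a whole number of metres with a small margin
        side = math.ceil(side + 2.0)
        extent = (side, side)
    trees = []
    for row in tree_coords.itertuples(index=False):
        cr = crown_radius if crown_radius is not None else max(
            CROWN_PER_DBH * row.dbh_cm, row.dbh_cm / 200.0
        )
        trees.append(
            Tree(int(row.id), float(row.x_m), float(row.y_m), float(row.dbh_cm),
                 float(row.height_m), cr)
        )
    return LandscapeGrid(extent, trees)


def build_empirical_like_grove(
    rng: np.random.Generator | None = None,
    n_trees: int = 20,
    extent: tuple[float, float] = (45.0, 45.0),
    max_span: float = 47.5,
    min_dist: float = 2.5,
    dbh: float = 15.0,
    height_range: tuple[float, float] = (4.0, 8.0),
) -> LandscapeGrid:
    """A ~0.2 ha grove of ~20 even-aged trees, pairwise 2.5-47.5 m apart.

    Positions are drawn inside a disc of diameter `max_span` centred in the
    landscape, which bounds every pairwise distance by construction; a
    minimum spacing of `min_dist` is enforced by rejection.
    """
    rng = np.random.default_rng(rng)
    centre = np.array(extent) / 2.0
    # disc bounded both by the pairwise-span cap and the landscape margin
    radius = min(max_span / 2.0, min(extent) / 2.0 - 0.5)
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n_trees:
        tries += 1
        if tries > 20_000:
            raise PlacementError("grove placement failed")
        r = radius * math.sqrt(rng.uniform())
        a = rng.uniform(0, 2 * math.pi)
        p = centre + r * np.array([math.cos(a), math.sin(a)])
        if all(np.hypot(*(p - q)) >= min_dist for q in pts):
            pts.append(p)
    trees = [
        Tree(k, p[0], p[1], dbh, rng.uniform(*height_range), CROWN_PER_DBH * dbh)
        for k, p in enumerate(pts)
    ]
    return LandscapeGrid(extent, trees)


# ----------------------------------------------------------------------
# stand dynamics
# ----------------------------------------------------------------------
def yoda_max_density(mean_mass: float, k: float | None = None) -> float:
    """Maximum stand density (trees/ha) on the -3/2 self-thinning line."""
    if k is None:
        k = YODA_K
    return (mean_mass / k) ** (-2.0 / 3.0)


def step_tree_dynamics(
    grid: LandscapeGrid,
    dt: float = 1.0,
    regen_rate: float = 0.15,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Advance the stand by `dt` years; returns ids of trees killed.

    Growth: every live tree's DBH increases by 0.13*dt cm, with crown radius
    and height following the DBH allometry. Self-thinning: while the stand
    density exceeds Yoda's -3/2 line for the current mean mass, a random
    live tree dies. Regeneration: Poisson(0.15 * N * dt) saplings appear on
    random open-ground patches, suspended while open ground is below 20%.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(rng)
    killed: list[int] = []
    live = grid.live_trees()
    for t in live:
        t.dbh += DBH_GROWTH_CM_YR * dt
        t.crown_radius = max(CROWN_PER_DBH * t.dbh, t.trunk_radius)
        t.height = HEIGHT_PER_DBH * t.dbh

    # Yoda self-thinning on the mean-mass proxy w = a * dbh^3; suppressed
    # (light) trees carry most of the mortality risk, as in real stands
    live = grid.live_trees()
    while live:
        mass = MASS_COEF * np.array([t.dbh**3 for t in live])
        if len(live) / grid.area_ha <= yoda_max_density(float(mass.mean())):
            break
        w = 1.0 / mass
        victim = live.pop(int(rng.choice(len(live), p=w / w.sum())))
        victim.alive = False
        killed.append(victim.id)

    grid.rebuild_fields()

    # natural regeneration on open ground
    n_live = grid.n_live_trees()
    if grid.open_fraction() >= MIN_OPEN_FRACTION and n_live > 0:
        n_new = rng.poisson(regen_rate * n_live * dt)
        if n_new:
            _recruit_on_open(grid, n_new, rng)
            grid.rebuild_fields()
    return killed


def _recruit_on_open(grid: LandscapeGrid, n: int, rng) -> int:
    """Add up to `n` saplings on random open patches; returns number added."""
    open_mask = (grid.n_layers == 0) & ~grid.trunk
    idx = np.flatnonzero(open_mask.ravel())
    if idx.size == 0:
        logger.warning("no open ground: recruited 0 of %d trees", n)
        return 0
    n_add = min(n, idx.size)
    if n_add < n:
        logger.warning("open ground limits recruitment to %d of %d trees", n_add, n)
    chosen = rng.choice(idx, size=n_add, replace=False)
    ii, jj = np.unravel_index(chosen, (grid.nx, grid.ny))
    for i, j in zip(ii, jj):
        x = (i + rng.uniform()) * grid.patch_size
        y = (j + rng.uniform()) * grid.patch_size
        grid.add_tree(x, y, SAPLING_DBH)
    return n_add


def apply_density_change(
    grid: LandscapeGrid,
    event: DensityChangeEvent,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Apply a deforestation/reforestation event in place.

    Returns ids of removed trees (deforestation) — their resident epiphytes
    must be killed by the caller holding the plant population.
    """
    rng = np.random.default_rng(rng)
    removed: list[int] = []
    if event.mode == "deforest":
        live = grid.live_trees()
        n_remove = len(live) - int(round((1.0 - event.magnitude) * len(live)))
        for t in rng.choice(live, size=n_remove, replace=False):
            t.alive = False
            removed.append(t.id)
    else:
        n_add = int(round(event.magnitude * grid.area_ha))
        added = 0
        # add saplings one by one so cover fields stay current
        open_mask = (grid.n_layers == 0) & ~grid.trunk
        idx = list(np.flatnonzero(open_mask.ravel()))
        rng.shuffle(idx)
        for flat in idx[:n_add]:
            i, j = np.unravel_index(flat, (grid.nx, grid.ny))
            x = (i + rng.uniform()) * grid.patch_size
            y = (j + rng.uniform()) * grid.patch_size
            grid.add_tree(x, y, SAPLING_DBH)
            added += 1
        if added < n_add:
            logger.warning("open ground limits planting to %d of %d trees", added, n_add)
    grid.rebuild_fields()
    return removed
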