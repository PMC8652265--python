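"""Synthetic urban landscape generator.

Emulates the inputs of the greening pipeline — a coarse (10 m) integer
land-use/land-cover raster, fine (1 m) binary tree-canopy and building
masks, a 100 m gridded population and a table of station air temperatures
at 21.00 — with the statistical structure the downstream analysis assumes:
a dense artificial core, a garden-rich residential ring, a forested
periphery and a water body on one edge, roads forming connected linear
corridors, and fine masks whose per-pixel cover fractions follow
class-conditional target densities.

All outputs are pure functions of (blueprint, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: integer codes of the base LULC classes
CLASS_CODES = {
    "building": 1,
    "road, path": 2,
    "sidewalk": 3,
    "traffic island": 4,
    "other impervious": 5,
    "garden": 6,
    "forest": 7,
    "water": 8,
}
CODE_TO_CLASS = {v: k for k, v in CLASS_CODES.items()}

#: base classes eligible for tree-canopy increase
CANDIDATE_CLASSES = (
    "building",
    "road, path",
    "sidewalk",
    "traffic island",
    "other impervious",
    "garden",
)

#: default areal fractions of the synthetic agglomeration
DEFAULT_CLASS_MIX = {
    "building": 0.13,
    "road, path": 0.08,
    "sidewalk": 0.04,
    "traffic island": 0.01,
    "other impervious": 0.06,
    "garden": 0.28,
    "forest": 0.33,
    "water": 0.07,
}

# class-conditional target cover densities of the fine masks, (mean, sd) of
# a clipped normal drawn per coarse pixel
DEFAULT_TREE_DENSITY = {
    "building": (0.08, 0.05),
    "road, path": (0.05, 0.04),
    "sidewalk": (0.15, 0.08),
    "traffic island": (0.25, 0.10),
    "other impervious": (0.08, 0.05),
    "garden": (0.45, 0.12),
    "forest": (0.88, 0.07),
    "water": (0.0, 0.0),
}
DEFAULT_BUILDING_DENSITY = {
    # 'building' uses a mixture, see _draw_building_density
    "building": (0.88, 0.05),
    "road, path": (0.02, 0.02),
    "sidewalk": (0.05, 0.04),
    "traffic island": (0.0, 0.0),
    "other impervious": (0.08, 0.06),
    "garden": (0.07, 0.05),
    "forest": (0.0, 0.0),
    "water": (0.0, 0.0),
}

#: fraction of 'building'-class pixels that are polygon-edge pixels with
#: low building cover (drawn uniform on [0.03, 0.22])
BUILDING_EDGE_FRACTION = 0.10

#: tree crown radius in fine cells (a 5 m spheric crown on a 1 m mask)
CROWN_RADIUS = 5


@dataclass(frozen=True)
class CityBlueprint:
    """Parameters of the synthetic city.

    side_m
        extent of the square study area in metres.
    coarse_res_m / fine_res_m
        cell sizes of the LULC raster and of the binary masks.
    class_mix
        base class -> target areal fraction; must sum to 1.
    pop_total
        total number of inhabitants to distribute.
    seed
        master seed; every output is deterministic given it.
    """

    side_m: int = 2400
    coarse_res_m: int = 10
    fine_res_m: int = 1
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    pop_total: int = 20000
    seed: int = 0

    def __post_init__(self):
        if self.side_m % self.coarse_res_m != 0:
            raise ValueError("side_m must be divisible by coarse_res_m")
        if self.coarse_res_m % self.fine_res_m != 0:
            raise ValueError("coarse_res_m must be divisible by fine_res_m")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class fractions must be non-negative")
        unknown = set(self.class_mix) - set(CLASS_CODES)
        if unknown:
            raise ValueError(f"unknown base classes: {sorted(unknown)}")
        if self.pop_total < 0:
            raise ValueError("pop_total must be >= 0")

    @property
    def n_coarse(self) -> int:
        return self.side_m // self.coarse_res_m

    @property
    def factor(self) -> int:
        """Fine cells per coarse cell along one axis."""
        return self.coarse_res_m // self.fine_res_m


def _quotas(class_mix: dict, n_cells: int) -> dict:
    """Largest-remainder apportionment of ``n_cells`` to the class mix.

    Every class with a positive target fraction receives at least one cell;
    if that is impossible the extent is too small for the blueprint.
    """
    positive = {c: f for c, f in class_mix.items() if f > 0}
    if len(positive) > n_cells:
        raise ValueError("extent too small to place all classes")
    raw = {c: f * n_cells for c, f in positive.items()}
    counts = {c: int(math.floor(x)) for c, x in raw.items()}
    # guarantee presence
    for c in counts:
        if counts[c] == 0:
            counts[c] = 1
    short = n_cells - sum(counts.values())
    order = sorted(positive, key=lambda c: raw[c] - math.floor(raw[c]), reverse=True)
    i = 0
    while short > 0:
        counts[order[i % len(order)]] += 1
        i += 1
        short -= 1
    while short < 0:  # presence guarantees may have overshot
        c = max(counts, key=lambda c: counts[c] - raw[c])
        if counts[c] <= 1:
            raise ValueError("extent too small to place all classes")
        counts[c] -= 1
        short += 1
    return counts


def make_lulc(blueprint: CityBlueprint) -> np.ndarray:
    """Generate the coarse integer LULC raster.

    The layout follows a concentric-ring agglomeration: water strip on the
    east edge, forest on the periphery, a grid of road corridors (plus one
    three-cell-wide highway) in the urban area, sidewalks hugging the
    roads, and the artificial classes filling the core with gardens in the
    outer residential ring.  Realized class fractions track ``class_mix``
    (exactly for water/forest, within a few cells for the rest).
    """
    n = blueprint.n_coarse
    rng = np.random.default_rng([blueprint.seed, 0])
    quotas = _quotas(blueprint.class_mix, n * n)
    grid = np.zeros((n, n), dtype=np.int16)  # 0 = unassigned

    rows, cols = np.indices((n, n))
    centre = (n - 1) / 2.0
    dist = np.hypot(rows - centre, cols - centre)

    # --- water: strip on the east edge, filled column by column
    n_water = quotas.get("water", 0)
    if n_water:
        full_cols, extra = divmod(n_water, n)
        if full_cols:
            grid[:, n - full_cols:] = CLASS_CODES["water"]
        if extra:
            grid[n - extra:, n - full_cols - 1] = CLASS_CODES["water"]

    # --- forest: the unassigned cells farthest from the centre
    n_forest = quotas.get("forest", 0)
    if n_forest:
        free = np.flatnonzero(grid.ravel() == 0)
        key = dist.ravel()[free] + rng.uniform(0, 0.5, free.size)
        chosen = free[np.argsort(key)[::-1][:n_forest]]
        grid.ravel()[chosen] = CLASS_CODES["forest"]

    # --- roads: grid of 1-wide corridors plus a 3-wide highway
    n_road = quotas.get("road, path", 0)
    if n_road:
        urban = grid == 0
        n_urban = int(urban.sum())
        # a grid of 1-wide lines with spacing s covers ~2/s of the urban
        # area; reserve ~3 rows for the highway
        line_quota = max(n_road - 3 * n, 1)
        spacing = min(max(int(round(2 * n_urban / line_quota)), 4), n)
        road = CLASS_CODES["road, path"]
        for r in range(spacing // 2, n, spacing):
            grid[r, urban[r, :]] = road
        urban = grid == 0
        for c in range(spacing // 2, n, spacing):
            grid[urban[:, c], c] = road
        # highway: three adjacent full rows through the middle, so that
        # interior road pixels surrounded by roads exist
        h0 = int(centre) - 1
        if n >= 8:
            sl = grid[h0:h0 + 3, :]
            sl[np.isin(sl, (0, road))] = road
            grid[h0:h0 + 3, :] = sl

    # --- remaining classes share the leftover cells, rescaled quotas
    rest = ["sidewalk", "building", "traffic island", "other impervious", "garden"]
    rest = [c for c in rest if quotas.get(c, 0) > 0]
    free_mask = grid == 0
    n_free = int(free_mask.sum())
    if rest:
        sub_mix = {c: quotas[c] for c in rest}
        tot = sum(sub_mix.values())
        sub_quotas = _quotas({c: q / tot for c, q in sub_mix.items()}, n_free) if n_free else {}

        # sidewalks first, preferring cells 4-adjacent to a road
        if "sidewalk" in sub_quotas:
            q = sub_quotas.pop("sidewalk")
            is_road = grid == CLASS_CODES["road, path"]
            adj = np.zeros_like(is_road)
            adj[:-1, :] |= is_road[1:, :]
            adj[1:, :] |= is_road[:-1, :]
            adj[:, :-1] |= is_road[:, 1:]
            adj[:, 1:] |= is_road[:, :-1]
            pool = np.flatnonzero((free_mask & adj).ravel())
            rng.shuffle(pool)
            take = pool[:q]
            grid.ravel()[take] = CLASS_CODES["sidewalk"]
            if take.size < q:  # fall back to any free cell
                free = np.flatnonzero(grid.ravel() == 0)
                rng.shuffle(free)
                grid.ravel()[free[: q - take.size]] = CLASS_CODES["sidewalk"]

        # the rest by jittered distance from the centre: buildings innermost,
        # gardens outermost
        free = np.flatnonzero(grid.ravel() == 0)
        key = dist.ravel()[free] + rng.normal(0, n / 10.0, free.size)
        free = free[np.argsort(key)]
        offset = 0
        for c in ("building", "other impervious", "traffic island", "garden"):
            q = sub_quotas.get(c, 0)
            if q:
                grid.ravel()[free[offset:offset + q]] = CLASS_CODES[c]
                offset += q
        if offset < free.size:  # rounding leftovers -> garden (or last class)
            fill = CLASS_CODES["garden"] if "garden" in sub_quotas else CLASS_CODES[rest[-1]]
            grid.ravel()[free[offset:]] = fill
    elif n_free:
        # degenerate mixes (e.g. single class): give leftovers to the
        # largest-quota class
        c = max(quotas, key=quotas.get)
        grid.ravel()[np.flatnonzero(grid.ravel() == 0)] = CLASS_CODES[c]

    return grid


def _draw_building_density(lulc: np.ndarray, rng: np.random.Generator,
                           density: dict) -> np.ndarray:
    """Per-coarse-pixel target building-cover fraction."""
    out = np.zeros(lulc.shape, dtype=float)
    for name, code in CLASS_CODES.items():
        mask = lulc == code
        k = int(mask.sum())
        if not k:
            continue
        mean, sd = density[name]
        vals = np.clip(rng.normal(mean, sd, k), 0.0, 1.0) if sd > 0 else np.full(k, mean)
        if name == "building":
            # polygon-edge pixels: a fraction of building-class pixels has
            # low cover and can still host a tree crown
            edge = rng.random(k) < BUILDING_EDGE_FRACTION
            vals[edge] = rng.uniform(0.03, 0.22, int(edge.sum()))
        out[mask] = vals
    return out


def _draw_tree_density(lulc: np.ndarray, rng: np.random.Generator,
                       density: dict) -> np.ndarray:
    out = np.zeros(lulc.shape, dtype=float)
    for name, code in CLASS_CODES.items():
        mask = lulc == code
        k = int(mask.sum())
        if not k:
            continue
        mean, sd = density[name]
        out[mask] = np.clip(rng.normal(mean, sd, k), 0.0, 1.0) if sd > 0 else mean
    return out


def _disk_stamps(factor: int, radius: int):
    """Boolean crown stamps, clipped to the block, for every centre."""
    ii, jj = np.indices((factor, factor))
    stamps = {}
    for ci in range(factor):
        for cj in range(factor):
            stamps[ci, cj] = (ii - ci) ** 2 + (jj - cj) ** 2 <= radius ** 2
    return stamps


def make_masks(lulc: np.ndarray, blueprint: CityBlueprint,
               tree_density: dict | None = None,
               building_density: dict | None = None):
    """Generate the fine-resolution binary (tree, building) masks.

    Buildings are rectangles, trees are pseudo-disk crowns of radius
    ``CROWN_RADIUS`` fine cells; both are placed block by block so that the
    realized per-coarse-pixel cover fraction equals the drawn class-
    conditional target exactly (up to whole fine cells).  Tree and building
    cells never overlap: buildings are placed first and crowns avoid them.
    """
    n = blueprint.n_coarse
    if lulc.shape != (n, n):
        raise ValueError("LULC raster does not match the blueprint grid")
    f = blueprint.factor
    tree_density = dict(DEFAULT_TREE_DENSITY, **(tree_density or {}))
    building_density = dict(DEFAULT_BUILDING_DENSITY, **(building_density or {}))
    rng = np.random.default_rng([blueprint.seed, 1])

    d_b = _draw_building_density(lulc, rng, building_density)
    d_t = _draw_tree_density(lulc, rng, tree_density)
    cells = f * f
    n_b = np.rint(d_b * cells).astype(int)
    n_t = np.minimum(np.rint(d_t * cells).astype(int), cells - n_b)

    tree = np.zeros((n * f, n * f), dtype=np.uint8)
    bld = np.zeros((n * f, n * f), dtype=np.uint8)
    stamps = _disk_stamps(f, CROWN_RADIUS)

    for i in range(n):
        for j in range(n):
            nb, nt = n_b[i, j], n_t[i, j]
            if nb == 0 and nt == 0:
                continue
            block_b = np.zeros((f, f), dtype=bool)
            if nb:
                w = min(max(int(round(math.sqrt(nb))), 1), f)
                h = min(math.ceil(nb / w), f)
                r0 = rng.integers(0, f - h + 1)
                c0 = rng.integers(0, f - w + 1)
                block_b[r0:r0 + h, c0:c0 + w] = True
                extra = int(block_b.sum()) - nb
                if extra > 0:  # trim random cells back to the exact count
                    on = np.flatnonzero(block_b.ravel())
                    block_b.ravel()[rng.choice(on, extra, replace=False)] = False
                elif extra < 0:
                    off = np.flatnonzero(~block_b.ravel())
                    block_b.ravel()[rng.choice(off, -extra, replace=False)] = True
            block_t = np.zeros((f, f), dtype=bool)
            if nt:
                avail = ~block_b
                for _ in range(16):
                    if int((block_t & avail).sum()) >= nt:
                        break
                    ci, cj = rng.integers(0, f, 2)
                    block_t |= stamps[int(ci), int(cj)]
                block_t &= avail
                got = int(block_t.sum())
                if got > nt:
                    on = np.flatnonzero(block_t.ravel())
                    block_t.ravel()[rng.choice(on, got - nt, replace=False)] = False
                elif got < nt:
                    off = np.flatnonzero((~block_t & avail).ravel())
                    block_t.ravel()[rng.choice(off, nt - got, replace=False)] = True
            sl = np.s_[i * f:(i + 1) * f, j * f:(j + 1) * f]
            bld[sl] = block_b
            tree[sl] = block_t
    return tree, bld


def make_population(lulc: np.ndarray, pop_total: int, seed: int,
                    coarse_res_m: int = 10, pop_res_m: int = 100) -> np.ndarray:
    """Distribute ``pop_total`` inhabitants on a coarse population grid.

    Cells are weighted by their count of 'building' pixels (plus a small
    garden weight for low-density housing), so the population concentrates
    in the built-up core.  Counts are non-negative integers summing exactly
    to ``pop_total``.
    """
    if pop_total < 0:
        raise ValueError("pop_total must be >= 0")
    if pop_res_m % coarse_res_m != 0:
        raise ValueError("population resolution must be a multiple of the LULC resolution")
    f = pop_res_m // coarse_res_m
    n = lulc.shape[0]
    if n % f != 0 or lulc.shape[1] % f != 0:
        raise ValueError("extent not divisible by the population cell size")
    m = n // f
    if pop_total == 0:
        return np.zeros((m, lulc.shape[1] // f), dtype=np.int64)

    def block_count(code):
        return (lulc == code).reshape(m, f, lulc.shape[1] // f, f).sum(axis=(1, 3))

    b = block_count(CLASS_CODES["building"])
    if b.sum() == 0:
        raise ValueError("no building pixels: population cannot be placed")
    g = block_count(CLASS_CODES["garden"])
    w = b.astype(float) + 0.02 * g
    rng = np.random.default_rng([seed, 2])
    flat = rng.multinomial(pop_total, (w / w.sum()).ravel())
    return flat.reshape(w.shape).astype(np.int64)


def make_station_series(n_stations: int, seed: int, n_days: int = 31,
                        start: str = "2018-07-01") -> pd.DataFrame:
    """Synthetic 21.00 air temperatures for a network of stations.

    Station 0 plays the rural reference (coolest); higher indices are
    progressively more urban.  The warmest day is nudged so that at least
    one day has a minimum-station temperature above 20 degC, which the
    reference-day selection rule requires.

    Returns a long table with columns ``date``, ``station_id``,
    ``temp_21h_c``.
    """
    if n_stations < 2:
        raise ValueError("at least two stations are required")
    rng = np.random.default_rng([seed, 3])
    base = rng.normal(19.5, 2.0, n_days)  # rural 21.00 temperature
    i_hot = int(np.argmax(base))
    base[i_hot] = max(base[i_hot], 20.8)
    offsets = np.sort(np.concatenate([[0.0], rng.uniform(0.5, 7.0, n_stations - 1)]))
    intensity = rng.uniform(0.6, 1.0, n_days)  # day-to-day UHI modulation
    dates = pd.date_range(start, periods=n_days, freq="D")
    records = []
    for d in range(n_days):
        temps = base[d] + offsets * intensity[d] + rng.normal(0, 0.15, n_stations)
        temps[0] = base[d]  # keep the rural station the daily minimum anchor
        for s in range(n_stations):
            records.append((dates[d], s, round(float(temps[s]), 2)))
    return pd.DataFrame(records, columns=["date", "station_id", "temp_21h_c"])
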