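"""Greening-scenario generation.

A pixel is a *candidate* for canopy increase iff its base class is one of
the six transformable classes ('building', 'road, path', 'sidewalk',
'traffic island', 'other impervious', 'garden'), its building cover is
under 25% (building bin 0), it is not already high-canopy, and — for
'road, path' — at least one of its eight Moore neighbours has a different
base class (no greening in the middle of a highway).

Scenarios transform a proportion p of the candidates to the refined code
with the same base class and the highest tree bin, under one of three
strategies:

random
    uniform sampling without replacement.
cluster
    greedily pick the candidate with the most high-canopy Moore
    neighbours; counts are dynamic (pixels transformed during the run
    count), ties broken uniformly at random.
scatter
    the same greedy rule minimizing the neighbour count.

All three are implemented as a single seeded ordering whose prefixes give
the scenario at each proportion, so the pixel set at p1 < p2 is nested in
the set at p2 for a fixed (strategy, seed).  p = 1 transforms every
candidate and is identical across strategies and seeds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .refine import RefinedLulcGrid, encode, is_high_canopy
from .synthetic_city import CANDIDATE_CLASSES, CLASS_CODES

#: the seven stochastic transformation proportions of the standard design
DEFAULT_PROPORTIONS = (0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.875)

STRATEGIES = ("random", "cluster", "scatter")

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class CandidateSet:
    """Pixels eligible for canopy increase, row-major sorted, no duplicates."""

    pixels: np.ndarray  # (k, 2) int array of (row, col)

    @property
    def total_count(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class ScenarioConfig:
    proportion: float
    strategy: str
    run_seed: int = 0

    def __post_init__(self):
        if not 0 < self.proportion <= 1:
            raise ValueError("proportion must lie in (0, 1]")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")


@dataclass(frozen=True)
class Scenario:
    config: ScenarioConfig
    transformed: np.ndarray  # (k, 2) pixel indices
    lulc: RefinedLulcGrid


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def find_candidates(refined: RefinedLulcGrid,
                    candidate_classes=CANDIDATE_CLASSES) -> CandidateSet:
    """Apply the eligibility rules and return the candidate pixel set."""
    base = refined.base_codes()
    codes = [CLASS_CODES[c] for c in candidate_classes]
    ok = np.isin(base, codes)
    ok &= refined.building_bins() == 0          # building cover under 25%
    ok &= refined.tree_bins() < refined.n_bins - 1  # not already high canopy

    road = CLASS_CODES["road, path"]
    if road in codes:
        # edge-replicated padding: out-of-bounds "neighbours" equal the
        # pixel itself, so only in-bounds neighbours can differ
        padded = np.pad(base, 1, mode="edge")
        any_diff = np.zeros(base.shape, dtype=bool)
        for di, dj in _MOORE:
            any_diff |= padded[1 + di:1 + di + base.shape[0],
                               1 + dj:1 + dj + base.shape[1]] != base
        ok &= (base != road) | any_diff
    return CandidateSet(np.argwhere(ok))


def sample_order(candidates: CandidateSet, refined: RefinedLulcGrid,
                 strategy: str, seed: int, k: int | None = None,
                 static: bool = False) -> np.ndarray:
    """Seeded candidate ordering; its k-prefix is the scenario at each p.

    For 'cluster'/'scatter' the ordering is the greedy dynamic-priority
    sequence: at each step the candidate with the maximal (minimal) number
    of high-canopy Moore neighbours is picked, neighbour counts being
    updated as picked pixels become high canopy (unless ``static``).
    """
    n_total = candidates.total_count
    if k is None:
        k = n_total
    k = min(k, n_total)
    rng = np.random.default_rng(seed)
    if strategy == "random":
        return candidates.pixels[rng.permutation(n_total)[:k]]
    if strategy not in ("cluster", "scatter"):
        raise ValueError(f"unknown strategy {strategy!r}")

    sign = 1.0 if strategy == "cluster" else -1.0
    nrow, ncol = refined.shape
    hc = np.pad(is_high_canopy(refined), 1, mode="constant")
    pix = candidates.pixels
    # initial neighbour counts via the padded high-canopy mask
    counts = np.zeros(n_total, dtype=float)
    pr, pc = pix[:, 0] + 1, pix[:, 1] + 1
    for di, dj in _MOORE:
        counts += hc[pr + di, pc + dj]

    cand_index = np.full((nrow + 2, ncol + 2), -1, dtype=np.int64)
    cand_index[pr, pc] = np.arange(n_total)

    active = sign * counts
    out = np.empty((k, 2), dtype=pix.dtype)
    for step in range(k):
        m = active.max()
        ties = np.flatnonzero(active == m)
        pick = int(ties[rng.integers(ties.size)]) if ties.size > 1 else int(ties[0])
        out[step] = pix[pick]
        active[pick] = -np.inf
        if not static:
            r, c = pix[pick, 0] + 1, pix[pick, 1] + 1
            hc[r, c] = True
            for di, dj in _MOORE:
                nb = cand_index[r + di, c + dj]
                if nb >= 0 and np.isfinite(active[nb]):
                    active[nb] += sign
    return out


def sample_pixels(candidates: CandidateSet, refined: RefinedLulcGrid,
                  config: ScenarioConfig, static: bool = False) -> np.ndarray:
    """Pixels transformed under ``config``: round(p * n) of the candidates."""
    if candidates.total_count == 0:
        raise ValueError("candidate set is empty")
    if config.proportion == 1.0:
        # single deterministic way to transform all candidates
        return candidates.pixels.copy()
    k = round_half_up(config.proportion * candidates.total_count)
    if k == 0:
        warnings.warn("proportion rounds to zero pixels; returning an empty set")
        return np.empty((0, 2), dtype=candidates.pixels.dtype)
    return sample_order(candidates, refined, config.strategy, config.run_seed,
                        k=k, static=static)


def apply_scenario(refined: RefinedLulcGrid, pixels: np.ndarray) -> RefinedLulcGrid:
    """Raise the selected pixels to the highest tree bin.

    Base class and building bin are preserved; all other pixels are
    untouched.  Idempotent.
    """
    pixels = np.asarray(pixels, dtype=int).reshape(-1, 2)
    codes = refined.codes.copy()
    if pixels.size:
        if (pixels < 0).any() or (pixels[:, 0] >= codes.shape[0]).any() \
                or (pixels[:, 1] >= codes.shape[1]).any():
            raise IndexError("pixel outside the raster extent")
        r, c = pixels[:, 0], pixels[:, 1]
        codes[r, c] = encode(codes[r, c] // 100, refined.n_bins - 1, codes[r, c] % 10)
    return RefinedLulcGrid(codes, refined.codebook, refined.n_bins)


def tally_by_class(pixels: np.ndarray, refined: RefinedLulcGrid) -> pd.Series:
    """Transformed-pixel counts keyed by original base class.

    All base classes of the codebook appear (zero counts included); the
    counts sum to the number of pixels.
    """
    pixels = np.asarray(pixels, dtype=int).reshape(-1, 2)
    classes = sorted({(rc.base_code, rc.base_class) for rc in refined.codebook.values()})
    index = [name for _, name in classes]
    tally = pd.Series(0, index=pd.Index(index, name="base_class"), name="n_transformed")
    if pixels.size:
        base = refined.base_codes()[pixels[:, 0], pixels[:, 1]]
        vals, counts = np.unique(base, return_counts=True)
        code_to_name = {code: name for code, name in classes}
        for v, cnt in zip(vals, counts):
            tally[code_to_name[int(v)]] += int(cnt)
    return tally
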