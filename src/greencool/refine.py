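"""LULC refinement by tree and building cover.

Each coarse LULC pixel is coupled with the fine binary masks to compute
its tree-cover and building-cover fractions; the fractions are binned into
``n_bins`` equally spaced intervals (default 4: 0-25, 25-50, 50-75 and
75-100%) and the pair of bins refines the base class, e.g. 'sidewalk with
high tree/low building cover'.  Bin intervals are half-open [a, b) with
the last bin closed at 1.0, so the highest tree bin and the >=75%
high-canopy rule coincide.

The refined code is ``base_code * 100 + tree_bin * 10 + building_bin`` —
compact, human readable and lossless for up to 10 bins.

Biophysical coefficients of a refined class: the shade coefficient is the
midpoint of its tree-cover bin (0.125, 0.375, 0.625, 0.875 for four
bins); the albedo is linearly interpolated between the base-class albedo
and the 'building' albedo by the building-bin midpoint; the crop
coefficient and the green-area flag follow the base class.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

from .synthetic_city import CLASS_CODES, CODE_TO_CLASS

N_BINS = 4


class RefinedClass(NamedTuple):
    base_code: int
    base_class: str
    tree_bin: int
    building_bin: int


@dataclass(frozen=True)
class CoverFractions:
    """Per-coarse-pixel tree and building cover fractions, both in [0, 1]."""

    tree_frac: np.ndarray
    building_frac: np.ndarray

    def __post_init__(self):
        if self.tree_frac.shape != self.building_frac.shape:
            raise ValueError("tree and building fraction rasters must share a shape")
        for a in (self.tree_frac, self.building_frac):
            if a.min() < 0 or a.max() > 1:
                raise ValueError("cover fractions must lie in [0, 1]")


@dataclass(frozen=True)
class RefinedLulcGrid:
    """Integer raster of refined codes plus the code -> class mapping."""

    codes: np.ndarray
    codebook: dict  # code -> RefinedClass
    n_bins: int = N_BINS

    def base_codes(self) -> np.ndarray:
        return self.codes // 100

    def tree_bins(self) -> np.ndarray:
        return (self.codes // 10) % 10

    def building_bins(self) -> np.ndarray:
        return self.codes % 10

    @property
    def shape(self):
        return self.codes.shape


def encode(base_code, tree_bin, building_bin):
    return base_code * 100 + tree_bin * 10 + building_bin


def decode(code):
    return code // 100, (code // 10) % 10, code % 10


def cover_fractions(fine_mask: np.ndarray, factor: int) -> np.ndarray:
    """Aggregate a fine binary mask to per-coarse-pixel cover fractions.

    Each coarse value is the arithmetic mean of its ``factor x factor``
    block of fine cells.
    """
    h, w = fine_mask.shape
    if h % factor or w % factor:
        raise ValueError("fine raster dimensions are not divisible by the aggregation factor")
    return (fine_mask.reshape(h // factor, factor, w // factor, factor)
            .mean(axis=(1, 3)))


def bin_fraction(frac, n_bins: int = N_BINS):
    """Bin a cover fraction into ``n_bins`` equally spaced intervals.

    Intervals are half-open except the last, e.g. with four bins 0.25 maps
    to bin 1 and 1.0 to bin 3.  Accepts scalars or arrays.
    """
    arr = np.asarray(frac, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("fractions must lie in [0, 1]")
    bins = np.minimum((arr * n_bins).astype(int), n_bins - 1)
    return bins if bins.ndim else int(bins)


def bin_midpoint(bin_index: int, n_bins: int = N_BINS) -> float:
    if not 0 <= bin_index < n_bins:
        raise ValueError(f"bin index must be in 0..{n_bins - 1}")
    return (bin_index + 0.5) / n_bins


def shade_coefficient(tree_bin: int, n_bins: int = N_BINS) -> float:
    """Shade of a refined class: the midpoint of its tree-cover bin."""
    return bin_midpoint(tree_bin, n_bins)


def albedo_coefficient(base_albedo: float, building_albedo: float,
                       building_bin: int, n_bins: int = N_BINS) -> float:
    """Albedo interpolated by building cover.

    A pixel whose building bin has midpoint m reflects like a mixture of
    (1 - m) base surface and m roof surface.
    """
    if not (0 <= base_albedo <= 1 and 0 <= building_albedo <= 1):
        raise ValueError("albedos must lie in [0, 1]")
    m = bin_midpoint(building_bin, n_bins)
    return (1 - m) * base_albedo + m * building_albedo


def refine_lulc(base: np.ndarray, covers: CoverFractions,
                class_names: dict | None = None,
                n_bins: int = N_BINS) -> RefinedLulcGrid:
    """Refine a base LULC raster with binned tree/building cover.

    The codebook registers every (tree bin, building bin) combination of
    each base class present, so grids transformed later (e.g. greening
    scenarios raising the tree bin) stay covered.
    """
    if base.shape != covers.tree_frac.shape:
        raise ValueError("base raster and cover fractions must share a shape")
    class_names = class_names or CODE_TO_CLASS
    present = np.unique(base)
    missing = [int(c) for c in present if int(c) not in class_names]
    if missing:
        raise ValueError(f"base codes missing from the class table: {missing}")
    tb = bin_fraction(covers.tree_frac, n_bins)
    bb = bin_fraction(covers.building_frac, n_bins)
    codes = encode(base.astype(np.int32), tb, bb)
    codebook = {}
    for c in present:
        c = int(c)
        for t in range(n_bins):
            for b in range(n_bins):
                codebook[encode(c, t, b)] = RefinedClass(c, class_names[c], t, b)
    return RefinedLulcGrid(codes.astype(np.int32), codebook, n_bins)


def is_high_canopy(refined: RefinedLulcGrid) -> np.ndarray:
    """True exactly where the tree bin is the highest (cover >= 75%)."""
    return refined.tree_bins() == refined.n_bins - 1


def load_base_properties(path=None) -> pd.DataFrame:
    """Base-class biophysical values (albedo, kc, green flag).

    Defaults ship with the package as CSV; pass ``path`` to override.
    """
    if path is None:
        with resources.files("greencool.data").joinpath(
                "biophysical_defaults.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    df["green_area"] = df["green_area"].astype(bool)
    return df.set_index("base_code")


def build_biophysical_table(refined: RefinedLulcGrid,
                            base_props: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-refined-code biophysical table.

    Columns: base_class, tree_bin, building_bin, shade, albedo, kc,
    green_area; indexed by refined code and covering the whole codebook.
    """
    if base_props is None:
        base_props = load_base_properties()
    n_bins = refined.n_bins
    building_albedo = float(base_props.loc[CLASS_CODES["building"], "albedo"]) \
        if CLASS_CODES["building"] in base_props.index else 0.20
    rows = []
    for code, rc in sorted(refined.codebook.items()):
        if rc.base_code not in base_props.index:
            raise ValueError(f"base code {rc.base_code} missing from the biophysical base table")
        props = base_props.loc[rc.base_code]
        rows.append({
            "code": code,
            "base_class": rc.base_class,
            "tree_bin": rc.tree_bin,
            "building_bin": rc.building_bin,
            "shade": shade_coefficient(rc.tree_bin, n_bins),
            "albedo": albedo_coefficient(float(props["albedo"]), building_albedo,
                                         rc.building_bin, n_bins),
            "kc": float(props["kc"]),
            "green_area": bool(props["green_area"]),
        })
    return pd.DataFrame(rows).set_index("code")
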