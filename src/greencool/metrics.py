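"""Landscape pattern metrics of the high-canopy class.

Adjacent (8-connected, matching the Moore neighbourhood used in scenario
sampling) pixels with high tree canopy cover form continuous canopy
patches.  Four metrics quantify their composition and configuration:

PLAND
    percentage of the landscape occupied by high-canopy pixels.
AREA_MN
    mean patch area (ha).
SHAPE_MN
    mean patch shape index, 0.25 * perimeter / sqrt(area) with area in
    m^2 and perimeter in m (1.0 for a single square cell).
ED
    edge density, total patch perimeter per landscape area (m/ha).

Perimeters count exposed cell edges; by default edges on the raster
boundary count (toggleable, as reference tools differ on this).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure


def pixels_to_hectares(n_pixels, cell_size: float):
    """Area of ``n_pixels`` square cells of side ``cell_size`` m, in ha."""
    return n_pixels * cell_size ** 2 / 1e4


@dataclass(frozen=True)
class PatchSet:
    """Labelled high-canopy patches with per-patch geometry."""

    labels: np.ndarray          # 0 = background, 1..n = patches
    areas_ha: np.ndarray        # per patch, ha
    perimeters_m: np.ndarray    # per patch, m
    cell_size: float
    landscape_area_ha: float

    @property
    def n_patches(self) -> int:
        return len(self.areas_ha)


@dataclass(frozen=True)
class MetricsRecord:
    pland: float
    area_mn: float
    shape_mn: float
    ed: float
    n_patches: int


def label_patches(high_canopy: np.ndarray, cell_size: float = 10.0,
                  connectivity: int = 8, count_boundary: bool = True) -> PatchSet:
    """Label patches and measure per-patch area and exposed perimeter.

    Perimeter is the length of cell edges bordering non-patch cells, plus
    the raster boundary if ``count_boundary``.
    """
    mask = np.asarray(high_canopy, dtype=bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = measure.label(mask, connectivity=2 if connectivity == 8 else 1)
    n = int(labels.max())
    landscape_area_ha = pixels_to_hectares(mask.size, cell_size)
    if n == 0:
        return PatchSet(labels, np.empty(0), np.empty(0), cell_size, landscape_area_ha)
    sizes = np.bincount(labels.ravel())[1:]
    areas_ha = pixels_to_hectares(sizes, cell_size)

    # constant-False padding makes boundary edges exposed; edge padding
    # replicates the cell so boundary edges never count
    padded = (np.pad(mask, 1, mode="constant", constant_values=False)
              if count_boundary else np.pad(mask, 1, mode="edge"))
    exposed = np.zeros(mask.shape, dtype=np.int32)
    h, w = mask.shape
    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        exposed += ~padded[1 + di:1 + di + h, 1 + dj:1 + dj + w]
    perims = np.bincount(labels.ravel(), weights=(exposed * mask).ravel())[1:]
    return PatchSet(labels, areas_ha, perims * cell_size, cell_size, landscape_area_ha)


def pland(patches: PatchSet, landscape_area_ha: float | None = None) -> float:
    """Percentage of the landscape covered by high-canopy patches."""
    area = patches.landscape_area_ha if landscape_area_ha is None else landscape_area_ha
    if area <= 0:
        raise ValueError("landscape area must be positive")
    return 100.0 * float(patches.areas_ha.sum()) / area


def area_mn(patches: PatchSet) -> float:
    """Mean patch area (ha); NaN when there are no patches."""
    if patches.n_patches == 0:
        return float("nan")
    return float(patches.areas_ha.mean())


def _min_perimeter_cells(n_cells: int) -> int:
    """Minimal perimeter (in cell edges) of a patch of n raster cells."""
    m = int(math.isqrt(n_cells))
    if m * m == n_cells:
        return 4 * m
    if n_cells <= m * (m + 1):
        return 4 * m + 2
    return 4 * m + 4


def shape_mn(patches: PatchSet, variant: str = "quarter") -> float:
    """Mean patch shape index; NaN when there are no patches.

    variant='quarter' (default): 0.25 * P / sqrt(A).
    variant='min_perimeter': P / P_min with P_min the smallest perimeter a
    patch of the same cell count can have (the integer-cell convention).
    """
    if patches.n_patches == 0:
        return float("nan")
    areas_m2 = patches.areas_ha * 1e4
    if variant == "quarter":
        si = 0.25 * patches.perimeters_m / np.sqrt(areas_m2)
    elif variant == "min_perimeter":
        n_cells = np.rint(areas_m2 / patches.cell_size ** 2).astype(int)
        p_min = np.array([_min_perimeter_cells(n) for n in n_cells]) * patches.cell_size
        si = patches.perimeters_m / p_min
    else:
        raise ValueError("variant must be 'quarter' or 'min_perimeter'")
    return float(si.mean())


def ed(patches: PatchSet, landscape_area_ha: float | None = None) -> float:
    """Edge density: total patch perimeter per landscape area (m/ha)."""
    area = patches.landscape_area_ha if landscape_area_ha is None else landscape_area_ha
    if area <= 0:
        raise ValueError("landscape area must be positive")
    return float(patches.perimeters_m.sum()) / area


def compute_metrics(high_canopy: np.ndarray, cell_size: float = 10.0,
                    connectivity: int = 8, count_boundary: bool = True,
                    shape_variant: str = "quarter") -> MetricsRecord:
    """All four metrics of a high-canopy mask in one record."""
    patches = label_patches(high_canopy, cell_size, connectivity, count_boundary)
    return MetricsRecord(
        pland=pland(patches),
        area_mn=area_mn(patches),
        shape_mn=shape_mn(patches, shape_variant),
        ed=ed(patches),
        n_patches=patches.n_patches,
    )
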