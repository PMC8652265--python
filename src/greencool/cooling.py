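"""Urban cooling simulation.

Air temperature on the refined LULC grid is simulated with a
shade/evapotranspiration/albedo heat-mitigation model:

* cooling capacity ``CC = w_s * shade + w_a * albedo + w_e * ETI`` with
  ``ETI = kc * ET0 / ET_max`` clipped to [0, 1];
* a park effect: near (within ``d_cool``) green patches of at least
  ``green_area_min_ha`` hectares, the heat-mitigation index is raised to
  the exp(-d/d_cool)-weighted mean of the green pixels' CC if that
  exceeds the pixel's own CC;
* unmixed temperature ``T = T_ref + (1 - HM) * UHI_max``, then air
  blending by a Gaussian moving average of radius ``r_mix`` (sigma =
  r_mix / 3, truncated at 3 sigma, renormalized at the raster border).

T_ref is the 21.00 temperature of the coolest station and UHI_max the
max-min station spread, on the admissible day (T_ref above a floor) with
the largest spread.  Reference evapotranspiration comes from the
temperature-based Hargreaves formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure


@dataclass(frozen=True)
class ClimateParams:
    """Scalar climate and model parameters.

    t_ref / uhi_max
        rural reference temperature and UHI magnitude at 21.00 (degC).
    et_max
        maximum reference evapotranspiration over the extent (mm/day);
        if None it is taken as the maximum of the ET0 raster.
    cc_weights
        (shade, albedo, evapotranspiration) weights, non-negative, sum 1.
    d_cool
        park cooling distance (m).
    r_mix
        air blending radius (m).
    green_area_min_ha
        minimum green-patch area for the park effect (ha).
    """

    t_ref: float
    uhi_max: float
    et_max: float | None = None
    cc_weights: tuple = (0.6, 0.2, 0.2)
    d_cool: float = 100.0
    r_mix: float = 500.0
    green_area_min_ha: float = 2.0

    def __post_init__(self):
        if self.uhi_max < 0:
            raise ValueError("uhi_max must be >= 0")
        w = np.asarray(self.cc_weights, dtype=float)
        if w.size != 3 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("cc_weights must be three non-negative fractions summing to 1")
        if self.d_cool <= 0 or self.r_mix <= 0:
            raise ValueError("d_cool and r_mix must be positive")


@dataclass(frozen=True)
class TemperatureField:
    """Heat-mitigation index in [0, 1] and air temperature (degC)."""

    hm: np.ndarray
    t_air: np.ndarray

    @property
    def t_mean(self) -> float:
        return float(self.t_air.mean())

    @property
    def t_max(self) -> float:
        return float(self.t_air.max())


def hargreaves_et0(t_min, t_avg, t_max, ra):
    """Reference evapotranspiration (mm/day) from daily temperatures.

    ``ET0 = 0.0023 * Ra * (T_avg + 17.8) * sqrt(T_max - T_min)``, floored
    at zero; ``ra`` is the extraterrestrial radiation expressed in mm/day
    of water equivalent.  Accepts scalars or broadcastable arrays.
    """
    t_min, t_avg, t_max = (np.asarray(x, dtype=float) for x in (t_min, t_avg, t_max))
    if np.any(t_min > t_max) or np.any(t_min > t_avg) or np.any(t_avg > t_max):
        raise ValueError("temperatures must satisfy t_min <= t_avg <= t_max")
    et0 = 0.0023 * np.asarray(ra, dtype=float) * (t_avg + 17.8) * np.sqrt(t_max - t_min)
    out = np.maximum(et0, 0.0)
    return float(out) if out.ndim == 0 else out


def select_reference_day(stations: pd.DataFrame, min_t_ref: float = 20.0):
    """Pick the reference day and derive (t_ref, uhi_max) from it.

    Among days whose minimum-station 21.00 temperature exceeds
    ``min_t_ref``, the day with the largest max-min spread is chosen;
    t_ref is that day's minimum and uhi_max its spread.

    ``stations`` is a long table with columns date, station_id,
    temp_21h_c (at least two stations).
    """
    if stations["station_id"].nunique() < 2:
        raise ValueError("at least two stations are required")
    daily = stations.groupby("date")["temp_21h_c"].agg(["min", "max"])
    admissible = daily[daily["min"] > min_t_ref]
    if admissible.empty:
        raise ValueError(f"no day with minimum station temperature above {min_t_ref} degC")
    spread = admissible["max"] - admissible["min"]
    day = spread.idxmax()
    return day, float(admissible.loc[day, "min"]), float(spread.loc[day])


def evapotranspiration_index(kc, et0, et_max):
    """ETI = kc * ET0 / ET_max, clipped to [0, 1]."""
    if et_max <= 0:
        raise ValueError("et_max must be positive")
    return np.clip(np.asarray(kc, dtype=float) * np.asarray(et0, dtype=float) / et_max,
                   0.0, 1.0)


def cooling_capacity(shade, albedo, eti, weights=(0.6, 0.2, 0.2)):
    """Weighted combination of the three cooling processes, in [0, 1]."""
    w = np.asarray(weights, dtype=float)
    if w.size != 3 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be three non-negative fractions summing to 1")
    return w[0] * np.asarray(shade, float) + w[1] * np.asarray(albedo, float) \
        + w[2] * np.asarray(eti, float)


def _park_kernel(d_cool: float, cell_size: float) -> np.ndarray:
    """exp(-d/d_cool) weights on the pixel offsets with d <= d_cool."""
    r = int(np.floor(d_cool / cell_size))
    oi, oj = np.mgrid[-r:r + 1, -r:r + 1]
    d = np.hypot(oi, oj) * cell_size
    k = np.exp(-d / d_cool)
    k[d > d_cool] = 0.0
    return k


def large_green_patches(green_mask: np.ndarray, cell_size: float,
                        min_area_ha: float) -> np.ndarray:
    """Mask of green pixels in 8-connected patches of at least min_area_ha."""
    labels = measure.label(green_mask.astype(bool), connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(green_mask, dtype=bool)
    sizes = np.bincount(labels.ravel())
    areas_ha = sizes * cell_size ** 2 / 1e4
    keep = areas_ha >= min_area_ha
    keep[0] = False
    return keep[labels]


def heat_mitigation(cc: np.ndarray, green_mask: np.ndarray, cell_size: float,
                    params: ClimateParams,
                    _green_big: np.ndarray | None = None) -> np.ndarray:
    """Cooling capacity adjusted for the park effect of large green areas.

    Where a qualifying green patch lies within ``d_cool`` of a pixel, the
    index becomes max(CC, weighted mean of green-pixel CC) with weights
    exp(-d/d_cool) over the green pixels within d_cool; elsewhere HM = CC.
    """
    if cc.shape != green_mask.shape:
        raise ValueError("cc and green mask must share a shape")
    gbig = large_green_patches(green_mask, cell_size, params.green_area_min_ha) \
        if _green_big is None else _green_big
    if not gbig.any():
        return cc.copy()
    kernel = _park_kernel(params.d_cool, cell_size)
    num = ndimage.convolve(np.where(gbig, cc, 0.0), kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(gbig.astype(float), kernel, mode="constant", cval=0.0)
    hm = cc.copy()
    reach = den > 0
    np.maximum(hm, np.divide(num, den, out=np.zeros_like(num), where=reach),
               out=hm, where=reach)
    return np.clip(hm, 0.0, 1.0)


def temperature_map(hm: np.ndarray, params: ClimateParams,
                    cell_size: float = 10.0) -> TemperatureField:
    """Air temperature from the heat-mitigation index.

    ``T_nomix = t_ref + (1 - HM) * uhi_max`` followed by a Gaussian
    moving average of radius ``r_mix`` (sigma = r_mix/3 truncated at
    3 sigma); the kernel is renormalized at the border so blending stays
    a convex combination and the [t_ref, t_ref + uhi_max] bounds hold.
    """
    if hm.min() < 0 or hm.max() > 1:
        raise ValueError("heat-mitigation index must lie in [0, 1]")
    t_nomix = params.t_ref + (1.0 - hm) * params.uhi_max
    sigma = params.r_mix / 3.0 / cell_size
    num = ndimage.gaussian_filter(t_nomix, sigma, truncate=3.0,
                                  mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(np.ones_like(t_nomix), sigma, truncate=3.0,
                                  mode="constant", cval=0.0)
    return TemperatureField(hm=hm, t_air=num / den)


def simulate(refined, biophys: pd.DataFrame, et0, params: ClimateParams,
             cell_size: float = 10.0,
             _green_big: np.ndarray | None = None) -> TemperatureField:
    """Full simulation on a refined LULC grid.

    Composes the per-class (shade, albedo, kc, green flag) lookup, the
    evapotranspiration index, cooling capacity, park effect and air
    blending.  ``et0`` may be a scalar or a raster; rasters of a different
    shape are bilinearly resampled to the LULC grid.
    """
    codes = refined.codes
    present = np.unique(codes)
    missing = [int(c) for c in present if int(c) not in biophys.index]
    if missing:
        raise ValueError(f"codes missing from the biophysical table: {missing}")
    top = int(biophys.index.max())
    shade_lut = np.zeros(top + 1)
    albedo_lut = np.zeros(top + 1)
    kc_lut = np.zeros(top + 1)
    green_lut = np.zeros(top + 1, dtype=bool)
    shade_lut[biophys.index] = biophys["shade"].to_numpy()
    albedo_lut[biophys.index] = biophys["albedo"].to_numpy()
    kc_lut[biophys.index] = biophys["kc"].to_numpy()
    green_lut[biophys.index] = biophys["green_area"].to_numpy()

    shade, albedo, kc = shade_lut[codes], albedo_lut[codes], kc_lut[codes]
    green = green_lut[codes]

    et0 = np.asarray(et0, dtype=float)
    if et0.ndim == 0:
        et0 = np.full(codes.shape, float(et0))
    elif et0.shape != codes.shape:
        et0 = ndimage.zoom(et0, (codes.shape[0] / et0.shape[0],
                                 codes.shape[1] / et0.shape[1]), order=1)
    et_max = params.et_max if params.et_max is not None else float(et0.max())
    eti = evapotranspiration_index(kc, et0, et_max)
    cc = cooling_capacity(shade, albedo, eti, params.cc_weights)
    hm = heat_mitigation(cc, green, cell_size, params, _green_big=_green_big)
    return temperature_map(hm, params, cell_size)
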