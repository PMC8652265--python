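"""Scenario-experiment orchestration.

Runs the full greening design — by default 7 proportions x 3 sampling
strategies x 10 runs plus the single deterministic 100% scenario, i.e.
211 scenarios — over one landscape, and aggregates temperatures,
landscape metrics, per-class transformation tallies and population
exposure into a tidy results table.

Per-run seeds derive from (master_seed, strategy, run) so that, for a
fixed strategy and run, the pixel sets at increasing proportions are
nested prefixes of a single seeded ordering; the whole experiment is a
pure function of (inputs, design, master_seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cooling, exposure as exposure_mod, metrics as metrics_mod
from . import refine as refine_mod
from . import scenario as scenario_mod
from . import synthetic_city as city_mod
from .cooling import ClimateParams, simulate
from .refine import RefinedLulcGrid, build_biophysical_table, is_high_canopy
from .scenario import (DEFAULT_PROPORTIONS, STRATEGIES, ScenarioConfig,
                       find_candidates, apply_scenario, round_half_up,
                       sample_order, tally_by_class)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentDesign:
    """The scenario grid: proportions x strategies x runs (+ full greening)."""

    proportions: tuple = DEFAULT_PROPORTIONS
    strategies: tuple = STRATEGIES
    runs_per_config: int = 10
    include_full: bool = True
    master_seed: int = 0

    @property
    def scenario_count(self) -> int:
        return (len(self.proportions) * len(self.strategies) * self.runs_per_config
                + (1 if self.include_full else 0))

    def derive_seed(self, strategy: str, run: int) -> int:
        """Deterministic per-(strategy, run) seed below 2**31."""
        s_idx = self.strategies.index(strategy)
        ss = np.random.SeedSequence([self.master_seed, s_idx, run])
        return int(ss.generate_state(1)[0]) % (2 ** 31)


@dataclass(frozen=True)
class ExperimentInputs:
    """One landscape plus everything the simulation needs."""

    refined: RefinedLulcGrid
    biophys: pd.DataFrame
    et0: np.ndarray | float
    params: ClimateParams
    population: np.ndarray
    cell_size: float = 10.0
    pop_factor: int = 10  # population cell size / LULC cell size


#: extraterrestrial radiation of a clear mid-latitude summer day,
#: expressed in mm/day of water equivalent
DEFAULT_RA = 16.7


def synthesize_inputs(blueprint: city_mod.CityBlueprint | None = None,
                      n_stations: int = 11,
                      params: ClimateParams | None = None) -> ExperimentInputs:
    """Build a complete input bundle from the synthetic-city generator.

    Generates the LULC raster, fine masks, population and a station
    series; refines the LULC; derives (t_ref, uhi_max) with the
    reference-day rule and an ET0 raster from the reference day's
    temperatures via Hargreaves (with a mild north-south gradient).
    ``params``, if given, overrides the derived climate parameters.
    """
    bp = blueprint or city_mod.CityBlueprint()
    lulc = city_mod.make_lulc(bp)
    tree, bld = city_mod.make_masks(lulc, bp)
    pop = city_mod.make_population(lulc, bp.pop_total, bp.seed,
                                   coarse_res_m=bp.coarse_res_m)
    stations = city_mod.make_station_series(n_stations, bp.seed)

    covers = refine_mod.CoverFractions(
        refine_mod.cover_fractions(tree, bp.factor),
        refine_mod.cover_fractions(bld, bp.factor))
    refined = refine_mod.refine_lulc(lulc, covers)
    biophys = build_biophysical_table(refined)

    _, t_ref, uhi_max = cooling.select_reference_day(stations)
    # reference-day diurnal cycle consistent with the 21.00 reading
    t_min, t_avg, t_maxd = t_ref - 4.0, t_ref + 3.0, t_ref + 10.0
    et0_scalar = cooling.hargreaves_et0(t_min, t_avg, t_maxd, DEFAULT_RA)
    n = refined.shape[0]
    gradient = np.linspace(0.95, 1.05, n)[:, None]  # cooler north, warmer south
    et0 = et0_scalar * np.broadcast_to(gradient, refined.shape).copy()

    if params is None:
        params = ClimateParams(t_ref=t_ref, uhi_max=uhi_max, et_max=float(et0.max()))
    return ExperimentInputs(refined=refined, biophys=biophys, et0=et0,
                            params=params, population=pop,
                            cell_size=float(bp.coarse_res_m),
                            pop_factor=100 // bp.coarse_res_m)


@dataclass
class ExperimentResult:
    results: pd.DataFrame
    baseline: dict
    design: ExperimentDesign
    maps: dict = field(default_factory=dict)


def _measure(inputs: ExperimentInputs, grid: RefinedLulcGrid, pixels,
             t_base: np.ndarray, green_big, thresholds) -> dict:
    field_ = simulate(grid, inputs.biophys, inputs.et0, inputs.params,
                      inputs.cell_size, _green_big=green_big)
    rec = metrics_mod.compute_metrics(is_high_canopy(grid), inputs.cell_size)
    cell_t = exposure_mod.cell_temperature(field_.t_air, inputs.pop_factor)
    expo = exposure_mod.exposure_table(cell_t, inputs.population, thresholds)
    tally = tally_by_class(pixels, grid)
    out = {
        "n_transformed": len(pixels),
        "t_mean": field_.t_mean,
        "t_min": float(field_.t_air.min()),
        "t_max": field_.t_max,
        "hm_max": float(field_.hm.max()),
        "heat_mitigation_max": float((t_base - field_.t_air).max()),
        "pland": rec.pland,
        "area_mn": rec.area_mn,
        "shape_mn": rec.shape_mn,
        "ed": rec.ed,
        "n_patches": rec.n_patches,
    }
    for _, row in expo.iterrows():
        out[f"exposed_gt_{row.threshold_c:g}"] = int(row.exposed_count)
    for cls, cnt in tally.items():
        out[f"n_{cls.replace(', ', '_').replace(' ', '_')}"] = int(cnt)
    out["_t_air"] = field_.t_air
    out["_codes"] = grid.codes
    return out


def run_experiment(inputs: ExperimentInputs,
                   design: ExperimentDesign | None = None,
                   thresholds=exposure_mod.DEFAULT_THRESHOLDS,
                   collect_maps: bool = False,
                   static_priority: bool = False) -> ExperimentResult:
    """Run every scenario of the design and tabulate the outcomes.

    One row per scenario run with the simulated mean/max temperature,
    maximum heat mitigation relative to the baseline landscape, the four
    landscape metrics, exposure counts per threshold and per-class
    transformation tallies.  Failed scenarios are logged and skipped.

    With ``collect_maps`` the per-configuration aggregate maps are
    returned as well: mean air temperature and mean heat mitigation, and
    the pixel-wise modal LULC code across the runs of a configuration.
    """
    design = design or ExperimentDesign()
    candidates = find_candidates(inputs.refined)
    if candidates.total_count == 0:
        raise ValueError("no candidate pixels in the landscape")
    # the green flag follows the base class, so the large-patch mask is
    # shared by every scenario of the landscape
    green_lut = np.zeros(int(inputs.biophys.index.max()) + 1, dtype=bool)
    green_lut[inputs.biophys.index] = inputs.biophys["green_area"].to_numpy()
    green_big = cooling.large_green_patches(green_lut[inputs.refined.codes],
                                            inputs.cell_size,
                                            inputs.params.green_area_min_ha)

    base_field = simulate(inputs.refined, inputs.biophys, inputs.et0,
                          inputs.params, inputs.cell_size, _green_big=green_big)
    base_rec = metrics_mod.compute_metrics(is_high_canopy(inputs.refined),
                                           inputs.cell_size)
    base_cell_t = exposure_mod.cell_temperature(base_field.t_air, inputs.pop_factor)
    base_expo = exposure_mod.exposure_table(base_cell_t, inputs.population, thresholds)
    baseline = {
        "t_mean": base_field.t_mean, "t_max": base_field.t_max,
        "pland": base_rec.pland, "area_mn": base_rec.area_mn,
        "shape_mn": base_rec.shape_mn, "ed": base_rec.ed,
        "exposure": base_expo,
    }

    k_max = round_half_up(max(design.proportions) * candidates.total_count) \
        if design.proportions else 0
    rows = []
    acc = {}  # (proportion, strategy) -> accumulators for aggregate maps
    for strategy in design.strategies:
        for run in range(design.runs_per_config):
            seed = design.derive_seed(strategy, run)
            order = sample_order(candidates, inputs.refined, strategy, seed,
                                 k=k_max, static=static_priority)
            for p in design.proportions:
                k = round_half_up(p * candidates.total_count)
                pixels = order[:k]
                try:
                    m = _measure(inputs, apply_scenario(inputs.refined, pixels),
                                 pixels, base_field.t_air, green_big, thresholds)
                except Exception:  # noqa: BLE001 - keep the batch running
                    logger.exception("scenario failed: p=%s strategy=%s run=%s",
                                     p, strategy, run)
                    continue
                t_air, codes = m.pop("_t_air"), m.pop("_codes")
                rows.append({"proportion": p, "strategy": strategy, "run": run,
                             "seed": seed, **m})
                if collect_maps:
                    a = acc.setdefault((p, strategy),
                                       {"t_sum": np.zeros_like(t_air),
                                        "codes": [], "n": 0})
                    a["t_sum"] += t_air
                    a["codes"].append(codes)
                    a["n"] += 1
    if design.include_full:
        pixels = candidates.pixels
        m = _measure(inputs, apply_scenario(inputs.refined, pixels), pixels,
                     base_field.t_air, green_big, thresholds)
        t_air, codes = m.pop("_t_air"), m.pop("_codes")
        rows.append({"proportion": 1.0, "strategy": "full", "run": 0,
                     "seed": design.master_seed, **m})
        if collect_maps:
            acc[(1.0, "full")] = {"t_sum": t_air.copy(), "codes": [codes], "n": 1}

    maps = {}
    if collect_maps:
        for key, a in acc.items():
            stack = np.stack(a["codes"])
            # pixel-wise mode of the LULC codes across runs
            mode_codes = stats.mode(stack, axis=0, keepdims=False).mode
            maps[key] = {"t_mean": a["t_sum"] / a["n"], "lulc_mode": mode_codes}
    return ExperimentResult(results=pd.DataFrame(rows), baseline=baseline,
                            design=design, maps=maps)


def confidence_interval(values, confidence: float = 0.95):
    """(mean, lower, upper) of a t-based confidence interval.

    With fewer than two values the interval is undefined and reported as
    missing (NaN bounds).
    """
    v = np.asarray(values, dtype=float)
    mean = float(v.mean()) if v.size else float("nan")
    if v.size < 2:
        return mean, float("nan"), float("nan")
    se = v.std(ddof=1) / np.sqrt(v.size)
    half = stats.t.ppf(0.5 + confidence / 2, v.size - 1) * se
    return mean, mean - half, mean + half


def strategy_contrast(results: pd.DataFrame, quantity: str,
                      reference: str = "random",
                      others=("scatter", "cluster"),
                      confidence: float = 0.95) -> pd.DataFrame:
    """Per-proportion differences reference - other of a run quantity.

    Runs are paired by run index; the mean difference and its t-based
    confidence interval are reported for every (proportion, contrast).
    """
    stoch = results[results["strategy"] != "full"]
    out = []
    for p in sorted(stoch["proportion"].unique()):
        sub = stoch[stoch["proportion"] == p]
        ref = sub[sub["strategy"] == reference].sort_values("run")
        for other in others:
            oth = sub[sub["strategy"] == other].sort_values("run")
            if len(ref) == 0 or len(ref) != len(oth):
                raise ValueError(f"incomplete design: no matched runs for "
                                 f"{reference} vs {other} at p={p}")
            diff = ref[quantity].to_numpy() - oth[quantity].to_numpy()
            mean, lo, hi = confidence_interval(diff, confidence)
            out.append({"proportion": p, "contrast": f"{reference}-{other}",
                        "mean_diff": mean, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(out)
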