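"""Population exposure to simulated heat.

The 10 m air-temperature raster is aggregated to the 100 m population
grid (mean of covered pixels by default, max as an alternative) and the
population of every cell whose temperature strictly exceeds a threshold
counts as exposed — whole-cell attribution, since the census is only
resolved at the population-cell level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = (21.0, 22.0, 23.0, 24.0, 25.0, 26.0)


def cell_temperature(t_air: np.ndarray, factor: int, agg: str = "mean") -> np.ndarray:
    """Aggregate the temperature raster to population cells.

    ``factor`` is the ratio of population to temperature resolution
    (e.g. 10 for 100 m cells on a 10 m raster).
    """
    h, w = t_air.shape
    if factor < 1 or h % factor or w % factor:
        raise ValueError("temperature raster does not tile the population grid")
    blocks = t_air.reshape(h // factor, factor, w // factor, factor)
    if agg == "mean":
        return blocks.mean(axis=(1, 3))
    if agg == "max":
        return blocks.max(axis=(1, 3))
    raise ValueError("agg must be 'mean' or 'max'")


def exposure_table(cell_temp: np.ndarray, population: np.ndarray,
                   thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Exposed population above each temperature threshold.

    Returns a frame with columns ``threshold_c``, ``exposed_count`` and
    ``exposed_share_pct``; counts are non-increasing in the threshold and
    use the strict inequality temperature > threshold.
    """
    if cell_temp.shape != population.shape:
        raise ValueError("temperature and population grids must share a shape")
    total = int(population.sum())
    rows = []
    for t in thresholds:
        count = int(population[cell_temp > t].sum())
        share = 100.0 * count / total if total else 0.0
        rows.append({"threshold_c": float(t), "exposed_count": count,
                     "exposed_share_pct": share})
    return pd.DataFrame(rows)
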