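"""Hydrological niche statistics from simulated uptake fields.

Two indices summarize what a rooting distribution is worth in water terms
when everything else about the plant is held fixed:

* the *total water uptake index* -- the sum of simulated uptake over all
  depths and days of a growing season for one rooting distribution;
* the *unique hydrological niche index* -- the water one distribution
  extracts in excess of the best competing distribution, summed over the
  index set:  sum_d max(U_i,d - max_{j != i} U_j,d, 0).

By default the per-depth uptake is first summed over the season (the index
runs over depth only); a per-(depth, day) mode keeps the time axis in the
index set, which can only enlarge the result (a max of sums never exceeds a
sum of maxes).  For exactly two distributions the positive parts obey
unique_i - unique_j = total_i - total_j as an arithmetic identity.
"""

from __future__ import annotations

import numpy as np

from .profiles import depth50
from .soilwater import UptakeField

__all__ = [
    "AGGREGATION_MODES",
    "total_water_uptake",
    "unique_niche",
    "mean_uptake_depth",
    "percent_difference",
    "round_percent",
]

AGGREGATION_MODES = ("per_season_depth", "per_depth_time")


def _uptake_matrix(u) -> np.ndarray:
    """(n_days, n_cells) per-cm uptake array from an UptakeField or array."""
    if isinstance(u, UptakeField):
        return u.uptake
    arr = np.asarray(u, dtype=float)
    return arr if arr.ndim == 2 else arr[np.newaxis, :]


def _dz(u) -> float:
    return u.dz if isinstance(u, UptakeField) else 1.0


def total_water_uptake(u) -> float:
    """Season total water uptake (cm) over all depths and days."""
    return float(_uptake_matrix(u).sum() * _dz(u))


def _indexed(u, mode: str) -> np.ndarray:
    m = _uptake_matrix(u) * _dz(u)
    if mode == "per_season_depth":
        return m.sum(axis=0)
    if mode == "per_depth_time":
        return m.ravel()
    raise ValueError(f"mode must be one of {AGGREGATION_MODES}")


def unique_niche(u_i, others, mode: str = "per_season_depth") -> float:
    """Water (cm) distribution i extracts in excess of every competitor.

    ``others`` is one field or a list of fields on the same grid.  In the
    default mode uptake is season-summed per depth before the comparison.
    """
    if isinstance(others, (UptakeField, np.ndarray)):
        others = [others]
    if len(others) == 0:
        raise ValueError("need at least one competing distribution")
    ui = _indexed(u_i, mode)
    comp = np.stack([_indexed(o, mode) for o in others])
    if comp.shape[1:] != ui.shape:
        raise ValueError("uptake fields are on mismatched grids")
    delta_max = ui - comp.max(axis=0)
    return float(np.clip(delta_max, 0.0, None).sum())


def mean_uptake_depth(u) -> float:
    """Depth (cm) above which half the season's water uptake occurred."""
    dz = _dz(u)
    per_cm = _uptake_matrix(u).sum(axis=0)
    return depth50(per_cm, dz=dz)


def percent_difference(total_i: float, total_j: float) -> float:
    """Signed percent difference 100 (total_i - total_j) / total_j."""
    if total_j <= 0:
        raise ValueError("reference total must be positive")
    return 100.0 * (total_i - total_j) / total_j


def round_percent(pct: float) -> int:
    """Nearest whole percent, for prose-style reporting."""
    return int(round(pct))
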