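"""Ecosystem-quality index construction, normalization and natural breaks.

The ecosystem quality index (EQI) summarises terrestrial vegetation
condition per grid cell as

    EQI = 100 * (LAI + GPP + FVC) / 3

with leaf-area index (LAI) and gross primary productivity (GPP) min-max
normalized to [0, 1] beforehand, and fractional vegetation cover (FVC)
derived from the enhanced vegetation index (EVI) by linear rescaling
between a bare-soil and a fully-vegetated reference value (the 5th and
95th EVI percentiles), clamped to [0, 1].

Class maps for display use Fisher-Jenks natural breaks: the optimal
contiguous partition of the sorted sample into k classes minimising the
total within-class sum of squared deviations, computed by dynamic
programming.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .raster import AlignedStack, RasterGrid

__all__ = [
    "DegenerateLayerError",
    "evi_proxies",
    "compute_fvc",
    "compute_eqi",
    "minmax_normalize",
    "jenks_breaks",
    "classify_breaks",
]


class DegenerateLayerError(ValueError):
    """A layer (or normalization domain) is constant or empty."""


def evi_proxies(evi: RasterGrid, p_soil: float = 5.0, p_veg: float = 95.0) -> tuple[float, float]:
    """Bare-soil and full-vegetation EVI reference values.

    Returns the ``p_soil``-th and ``p_veg``-th percentiles of the unmasked
    EVI cells (linear-interpolation percentile definition).
    """
    if not p_soil < p_veg:
        raise ValueError("p_soil must be < p_veg")
    vals = evi.unmasked()
    if vals.size < 2:
        raise DegenerateLayerError("need at least two unmasked cells")
    lo, hi = np.percentile(vals, [p_soil, p_veg], method="linear")
    if not lo < hi:
        raise DegenerateLayerError("constant layer: soil and vegetation proxies coincide")
    return float(lo), float(hi)


def compute_fvc(evi: RasterGrid, evi_soil: float, evi_veg: float) -> RasterGrid:
    """Fractional vegetation cover: (EVI - EVI_soil)/(EVI_veg - EVI_soil), clamped to [0, 1]."""
    if not evi_soil < evi_veg:
        raise ValueError("evi_soil must be < evi_veg")
    fvc = np.clip((evi.values - evi_soil) / (evi_veg - evi_soil), 0.0, 1.0)
    return evi.with_values(fvc)


def compute_eqi(lai: RasterGrid, gpp: RasterGrid, fvc: RasterGrid) -> RasterGrid:
    """EQI = 100 * mean(LAI, GPP, FVC), all inputs already in [0, 1].

    The output mask is the union of the three input masks.
    """
    lai.require_aligned(gpp, "GPP")
    lai.require_aligned(fvc, "FVC")
    mask = lai.mask | gpp.mask | fvc.mask
    for name, g in (("LAI", lai), ("GPP", gpp), ("FVC", fvc)):
        v = g.values[~mask]
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError(f"{name} must be normalized to [0, 1] before EQI")
    eqi = 100.0 * (lai.values + gpp.values + fvc.values) / 3.0
    return lai.with_values(eqi, mask)


def minmax_normalize(
    data: RasterGrid | AlignedStack,
    target_lo: float = 0.0,
    target_hi: float = 1.0,
    domain: Literal["per-epoch", "pooled-epochs"] = "pooled-epochs",
):
    """Affine min-max rescale onto [target_lo, target_hi].

    For a stack, ``domain="pooled-epochs"`` (the default) takes one min/max
    over all epochs so that levels stay comparable across years;
    ``"per-epoch"`` rescales each epoch independently.
    """
    def _rescale(values: np.ndarray, mask: np.ndarray, lo: float, hi: float) -> np.ndarray:
        if not lo < hi:
            raise DegenerateLayerError("constant normalization domain")
        out = (values - lo) / (hi - lo) * (target_hi - target_lo) + target_lo
        return np.where(mask, values, out)

    if isinstance(data, RasterGrid):
        v = data.unmasked()
        if v.size == 0:
            raise DegenerateLayerError("all cells masked")
        return data.with_values(_rescale(data.values, data.mask, v.min(), v.max()))

    if domain == "per-epoch":
        return AlignedStack([minmax_normalize(g, target_lo, target_hi) for g in data.grids])
    pooled = np.concatenate([g.unmasked() for g in data.grids])
    if pooled.size == 0:
        raise DegenerateLayerError("all cells masked")
    lo, hi = pooled.min(), pooled.max()
    return data.map(lambda v, m: _rescale(v, m, lo, hi))


def jenks_breaks(values, k: int) -> list[float]:
    """Fisher-Jenks optimal natural breaks.

    Partitions the sorted sample into ``k`` contiguous classes minimising
    the total within-class sum of squared deviations and returns the
    ``k - 1`` interior break values (the largest value of each class but
    the last). Ties in the optimum are resolved toward the smallest break
    indices.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(x).size
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct values")
    n = x.size
    # Prefix sums give O(1) within-class SSD for any contiguous run.
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: int, j: int) -> float:
        # sum of squared deviations of x[i:j]
        m = j - i
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / m

    INF = np.inf
    # cost[c][j]: minimal total SSD of splitting x[:j] into c classes
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                if cost[c - 1, i] == INF:
                    continue
                val = cost[c - 1, i] + ssd(i, j)
                if val < best - 1e-12:
                    best, arg = val, i
            cost[c, j] = best
            split[c, j] = arg
    # Backtrack the class boundaries.
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = split[c, j]
        bounds.append(j)
    bounds = bounds[::-1]  # [0, i1, ..., n]
    return [float(x[b - 1]) for b in bounds[1:-1]]


def classify_breaks(grid: RasterGrid, breaks: list[float]) -> RasterGrid:
    """Map values to 0-based class indices given interior break values.

    A cell belongs to class c if value <= breaks[c], else to the last class.
    """
    idx = np.searchsorted(np.asarray(breaks, dtype=float), grid.values, side="left")
    return grid.with_values(idx.astype(float))
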