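"""Four-quadrant classification of paired human-nature change.

Between two epochs, each cell's change in human footprint (dHFI) and in
ecosystem quality (dEQI) places it in one of four evolution types:

* coordination      (+, +)  both systems advance together
* good_for_nature   (-, +)  human pressure retreats, quality improves
* degradation       (-, -)  both decline
* conflict          (+, -)  pressure intensifies while quality declines

Cells whose change is smaller in magnitude than a fraction (default 10%)
of the period-wide standard deviation of that change raster are declared
``insignificant`` — too small to carry a signed direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .raster import AlignedStack, RasterGrid

__all__ = ["QUADRANT_CODES", "PeriodChange", "QuadrantMap", "period_change",
           "classify_quadrant", "area_proportions"]

#: Stable integer codes for the categorical map.
QUADRANT_CODES = {
    "coordination": 1,
    "good_for_nature": 2,
    "degradation": 3,
    "conflict": 4,
    "insignificant": 0,
}
_CODE_NAMES = {v: k for k, v in QUADRANT_CODES.items()}


@dataclass
class PeriodChange:
    """Cellwise index changes over one period plus their change-SDs."""

    dhfi: RasterGrid
    deqi: RasterGrid
    sigma_dhfi: float
    sigma_deqi: float


@dataclass
class QuadrantMap:
    """Categorical grid of quadrant codes (see :data:`QUADRANT_CODES`)."""

    codes: RasterGrid

    def names(self) -> np.ndarray:
        """Object array of class names (masked cells -> '')."""
        out = np.full(self.codes.shape, "", dtype=object)
        valid = ~self.codes.mask
        out[valid] = [_CODE_NAMES[int(c)] for c in self.codes.values[valid]]
        return out

    def region_mask(self, name: str) -> np.ndarray:
        """Boolean mask of unmasked cells carrying the named class."""
        return (~self.codes.mask) & (self.codes.values == QUADRANT_CODES[name])


def period_change(hfi: AlignedStack, eqi: AlignedStack, t0, t1) -> PeriodChange:
    """Cellwise differences t1 - t0 and the SDs of the change rasters."""
    h0, h1 = hfi.grid(t0), hfi.grid(t1)
    e0, e1 = eqi.grid(t0), eqi.grid(t1)
    h0.require_aligned(e0, "EQI stack")
    mask = h0.mask | e0.mask
    dh = h0.with_values(h1.values - h0.values, mask)
    de = e0.with_values(e1.values - e0.values, mask)
    return PeriodChange(dh, de,
                        sigma_dhfi=float(np.std(dh.unmasked())),
                        sigma_deqi=float(np.std(de.unmasked())))


def classify_quadrant(
    change: PeriodChange,
    sigma_fraction: float = 0.1,
    significance: Literal["or", "and"] = "or",
) -> QuadrantMap:
    """Assign each cell a quadrant, with the significance rule.

    A change is significant when its magnitude is at least
    ``sigma_fraction`` times the SD of that change raster (a change exactly
    at the threshold counts as significant). Under ``significance="or"``
    (the default) a cell failing the test on either axis is
    ``insignificant`` — quadrant membership requires a signed direction on
    both axes; ``"and"`` demands failure on both axes before declaring a
    cell insignificant.

    With a zero change-SD every nonzero change is significant.
    """
    if sigma_fraction <= 0:
        raise ValueError("sigma_fraction must be > 0")
    dh, de = change.dhfi.values, change.deqi.values
    small_h = np.abs(dh) < sigma_fraction * change.sigma_dhfi
    small_e = np.abs(de) < sigma_fraction * change.sigma_deqi
    insig = (small_h | small_e) if significance == "or" else (small_h & small_e)

    codes = np.full(dh.shape, QUADRANT_CODES["insignificant"], dtype=float)
    sig = ~insig
    codes[sig & (dh > 0) & (de > 0)] = QUADRANT_CODES["coordination"]
    codes[sig & (dh < 0) & (de > 0)] = QUADRANT_CODES["good_for_nature"]
    codes[sig & (dh < 0) & (de < 0)] = QUADRANT_CODES["degradation"]
    codes[sig & (dh > 0) & (de < 0)] = QUADRANT_CODES["conflict"]
    # A significant cell with an exactly-zero axis (possible only when that
    # axis' sigma is 0) carries no direction there; keep it insignificant.
    codes[sig & ((dh == 0) | (de == 0))] = QUADRANT_CODES["insignificant"]
    return QuadrantMap(change.dhfi.with_values(codes))


def area_proportions(qmap: QuadrantMap, region_mask: np.ndarray | None = None) -> pd.Series:
    """Percentage of (optionally region-restricted) unmasked cells per class.

    Returns a Series indexed by class name, summing to 100.
    """
    valid = ~qmap.codes.mask
    if region_mask is not None:
        valid &= np.asarray(region_mask, dtype=bool)
    total = int(valid.sum())
    if total == 0:
        raise ValueError("empty region: no unmasked cells selected")
    vals = qmap.codes.values[valid]
    return pd.Series(
        {name: 100.0 * float(np.sum(vals == code)) / total
         for name, code in QUADRANT_CODES.items()},
        name="percent",
    )
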