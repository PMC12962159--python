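"""Coupling-coordination-degree (CCD) model for two subsystems.

Given human-footprint and ecosystem-quality layers rescaled to [0, 1],
the model computes per cell

    C   = 2 * sqrt(HFI * EQI) / (HFI + EQI)      coupling degree
    T   = a * HFI + b * EQI                      comprehensive index
    CCD = sqrt(C * T)                            coupling coordination degree

with a = b = 0.5 by default (human and natural systems weighted equally).
C is 1 when the two subsystem levels are equal and falls toward 0 as they
diverge; T measures their joint level; CCD combines balance and level on a
[0, 1] scale classified into five coordination categories:

    [0.0, 0.2) severely disordered
    [0.2, 0.4) nearly disordered
    [0.4, 0.6) primarily coordinated
    [0.6, 0.8) moderately coordinated
    [0.8, 1.0] highly coordinated

Intervals are half-open with the top interval closed. The canonical form
above (with the radicals) is the default; ``variant="literal"`` computes
C = 2*HFI*EQI/(HFI+EQI) and CCD = C*T instead, for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = ["CCD_LEVELS", "CCDParams", "CCDResult", "coupling_degree",
           "comprehensive_index", "ccd", "classify_ccd", "ccd_pipeline"]

#: (lower bound, name) of the five coordination levels, ascending.
CCD_LEVELS = [
    (0.0, "severely disordered"),
    (0.2, "nearly disordered"),
    (0.4, "primarily coordinated"),
    (0.6, "moderately coordinated"),
    (0.8, "highly coordinated"),
]

Variant = Literal["canonical", "literal"]


@dataclass
class CCDParams:
    """Subsystem weights (a for HFI, b for EQI; a + b = 1) and formula variant."""

    a: float = 0.5
    b: float = 0.5
    variant: Variant = "canonical"

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or abs(self.a + self.b - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")


@dataclass
class CCDResult:
    C: RasterGrid
    T: RasterGrid
    ccd: RasterGrid
    level: RasterGrid
    proportions: pd.Series
    params: CCDParams = field(default_factory=CCDParams)


def _check01(grid: RasterGrid, name: str) -> None:
    v = grid.unmasked()
    if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
        raise ValueError(f"{name} must be pre-scaled to [0, 1]")


def coupling_degree(hfi01: RasterGrid, eqi01: RasterGrid,
                    variant: Variant = "canonical") -> RasterGrid:
    """Coupling degree C of two [0, 1] layers; C(x, x) = 1 for x > 0 (canonical).

    Where both inputs are 0 the degree is defined as 0 (no coupling
    without activity or quality).
    """
    hfi01.require_aligned(eqi01, "EQI")
    _check01(hfi01, "HFI")
    _check01(eqi01, "EQI")
    h, e = hfi01.values, eqi01.values
    denom = h + e
    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "canonical":
            c = 2.0 * np.sqrt(np.clip(h * e, 0.0, None)) / denom
        else:
            c = 2.0 * h * e / denom
    c = np.where(denom > 0, c, 0.0)
    return hfi01.with_values(np.clip(c, 0.0, 1.0), hfi01.mask | eqi01.mask)


def comprehensive_index(hfi01: RasterGrid, eqi01: RasterGrid,
                        params: CCDParams | None = None) -> RasterGrid:
    """Comprehensive level T = a*HFI + b*EQI."""
    params = params or CCDParams()
    hfi01.require_aligned(eqi01, "EQI")
    _check01(hfi01, "HFI")
    _check01(eqi01, "EQI")
    t = params.a * hfi01.values + params.b * eqi01.values
    return hfi01.with_values(t, hfi01.mask | eqi01.mask)


def ccd(C: RasterGrid, T: RasterGrid, variant: Variant = "canonical") -> RasterGrid:
    """CCD = sqrt(C*T) (canonical) or C*T (literal); monotone in each input."""
    C.require_aligned(T, "T")
    prod = np.clip(C.values * T.values, 0.0, None)
    vals = np.sqrt(prod) if variant == "canonical" else prod
    return C.with_values(np.clip(vals, 0.0, 1.0), C.mask | T.mask)


def classify_ccd(ccd_grid: RasterGrid) -> tuple[RasterGrid, pd.Series]:
    """Five-level classification of a CCD grid plus class percentages.

    Returns (level grid with 0-based codes ascending with coordination,
    Series of percentages indexed by level name).
    """
    v = ccd_grid.unmasked()
    if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
        raise ValueError("CCD must lie in [0, 1]")
    bounds = [lo for lo, _ in CCD_LEVELS[1:]]
    codes = np.searchsorted(bounds, ccd_grid.values, side="right").astype(float)
    level = ccd_grid.with_values(codes)
    valid = ~level.mask
    total = max(int(valid.sum()), 1)
    props = pd.Series(
        {name: 100.0 * float(np.sum(codes[valid] == i)) / total
         for i, (_, name) in enumerate(CCD_LEVELS)},
        name="percent",
    )
    return level, props


def ccd_pipeline(hfi01: RasterGrid, eqi01: RasterGrid,
                 params: CCDParams | None = None) -> CCDResult:
    """Full C / T / CCD / level computation for one epoch."""
    params = params or CCDParams()
    C = coupling_degree(hfi01, eqi01, params.variant)
    T = comprehensive_index(hfi01, eqi01, params)
    D = ccd(C, T, params.variant)
    level, props = classify_ccd(D)
    return CCDResult(C, T, D, level, props, params)
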