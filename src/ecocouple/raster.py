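"""Georeferenced single-band grids and aligned multi-epoch stacks.

A :class:`RasterGrid` is the unit of all spatial inputs and outputs: one
2-D array of cell values (north-up, row-major), a boolean nodata mask, an
affine placement ``(origin_x, origin_y, cell_size)`` and a CRS label.
An :class:`AlignedStack` is an epoch-ordered list of grids sharing shape,
placement and mask, which is what every change/coupling operation consumes.

I/O supports two formats:

* TIFF pixel data (via :mod:`tifffile`) with a sidecar ``<name>.json``
  carrying the georeferencing, epoch and nodata value;
* ESRI ASCII grid (``.asc``), a plain-text raster interchange format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["RasterGrid", "AlignedStack", "AlignmentError", "read_raster", "write_raster"]

_NODATA_DEFAULT = -9999.0


class AlignmentError(ValueError):
    """Raised when grids that must share geometry do not."""


@dataclass
class RasterGrid:
    """One georeferenced 2-D layer with a nodata mask.

    Parameters
    ----------
    values : ndarray
        2-D float array of cell values. Entries under the mask are ignored.
    mask : ndarray of bool
        True where the cell is nodata. Same shape as ``values``.
    transform : tuple
        ``(origin_x, origin_y, cell_size)`` — upper-left corner and square
        cell size in CRS units.
    crs_id : str
        CRS label, e.g. ``"EPSG:4326"``.
    epoch : int | str | None
        Year label for time-stacked layers.
    """

    values: np.ndarray
    mask: np.ndarray | None = None
    transform: tuple[float, float, float] = (0.0, 0.0, 1.0)
    crs_id: str = "EPSG:4326"
    epoch: int | str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must equal values shape")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("unmasked values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def unmasked(self) -> np.ndarray:
        """1-D array of the valid cell values."""
        return self.values[~self.mask]

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        """New grid with the same geometry but different values/mask."""
        return replace(self, values=np.asarray(values, dtype=float),
                       mask=self.mask.copy() if mask is None else np.asarray(mask, bool))

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.transform, other.transform)
                and self.crs_id == other.crs_id)

    def require_aligned(self, other: "RasterGrid", name: str = "grid") -> None:
        if not self.same_geometry(other):
            raise AlignmentError(f"{name} is not aligned: shape/transform/CRS differ")


def _union_mask(grids: Iterable[RasterGrid]) -> np.ndarray:
    grids = list(grids)
    m = grids[0].mask.copy()
    for g in grids[1:]:
        m |= g.mask
    return m


@dataclass
class AlignedStack:
    """Epoch-ordered grids sharing shape, transform, CRS and nodata mask."""

    grids: list[RasterGrid] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.grids:
            raise ValueError("stack must contain at least one grid")
        ref = self.grids[0]
        for g in self.grids[1:]:
            ref.require_aligned(g, name=f"epoch {g.epoch}")
        epochs = self.epochs
        if any(e is None for e in epochs):
            raise ValueError("every grid in a stack needs an epoch label")
        if list(epochs) != sorted(epochs):
            raise ValueError("epochs must be strictly increasing")
        if len(set(epochs)) != len(epochs):
            raise ValueError("duplicate epoch labels")
        # Conservative shared mask: a cell must be observed in all epochs.
        shared = _union_mask(self.grids)
        self.grids = [g.with_values(g.values, shared) for g in self.grids]

    @property
    def epochs(self) -> list:
        return [g.epoch for g in self.grids]

    @property
    def shape(self) -> tuple[int, int]:
        return self.grids[0].shape

    @property
    def mask(self) -> np.ndarray:
        return self.grids[0].mask

    def grid(self, epoch) -> RasterGrid:
        for g in self.grids:
            if g.epoch == epoch:
                return g
        raise KeyError(f"epoch {epoch!r} not in stack {self.epochs}")

    def as_array(self) -> np.ndarray:
        """(n_epochs, rows, cols) float array with NaN under the mask."""
        out = np.stack([g.values for g in self.grids]).astype(float)
        out[:, self.mask] = np.nan
        return out

    def map(self, fn) -> "AlignedStack":
        """Apply ``fn(values, mask) -> values`` per epoch, keeping geometry."""
        return AlignedStack([g.with_values(fn(g.values, g.mask)) for g in self.grids])


# ---------------------------------------------------------------------------
# I/O


def write_raster(grid: RasterGrid, path: str | Path, nodata: float = _NODATA_DEFAULT) -> Path:
    """Write a grid as TIFF + JSON sidecar, or as ESRI ASCII grid for ``.asc``."""
    path = Path(path)
    vals = grid.values.copy()
    vals[grid.mask] = nodata
    if path.suffix.lower() == ".asc":
        ox, oy, cs = grid.transform
        rows, cols = grid.shape
        header = (f"ncols {cols}\nnrows {rows}\nxllcorner {ox}\n"
                  f"yllcorner {oy - rows * cs}\ncellsize {cs}\nNODATA_value {nodata}\n")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.10g")
    else:
        import tifffile

        tifffile.imwrite(path, vals.astype(np.float32))
        meta = {"transform": list(grid.transform), "crs_id": grid.crs_id,
                "epoch": grid.epoch, "nodata": nodata}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_raster(path: str | Path, epoch=None) -> RasterGrid:
    """Read a grid written by :func:`write_raster`."""
    path = Path(path)
    if path.suffix.lower() == ".asc":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = vals.reshape(int(header["nrows"]), int(header["ncols"]))
        nodata = header.get("nodata_value", _NODATA_DEFAULT)
        cs = header["cellsize"]
        transform = (header["xllcorner"], header["yllcorner"] + header["nrows"] * cs, cs)
        return RasterGrid(vals, mask=vals == nodata, transform=transform, epoch=epoch)
    import tifffile

    vals = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    nodata = meta.get("nodata", _NODATA_DEFAULT)
    return RasterGrid(vals, mask=vals == nodata,
                      transform=tuple(meta.get("transform", (0.0, 0.0, 1.0))),
                      crs_id=meta.get("crs_id", "EPSG:4326"),
                      epoch=meta.get("epoch", epoch))
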