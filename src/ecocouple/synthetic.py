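"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators cover the three kinds of input the analysis consumes:

* :func:`generate_coupled_stacks` — paired human-footprint (HFI) and
  ecosystem-quality (EQI) raster time series on a 0-100 scale, with
  rectangular blocks planted as the four quadrant evolution types plus an
  insignificant-change class. Defaults emulate a rapidly urbanising
  region: HFI rising from the mid-30s by roughly ten points over two
  decades while EQI drifts down from around 50, conflict areas outweighing
  coordinated ones roughly 5:3.
* :func:`generate_sem_table` — driver indicator tables simulated from a
  known latent path model (latents drawn recursively along a
  lower-triangular coefficient matrix, indicators as loading x latent plus
  measurement noise), returning the analytic standardized truth alongside
  the data so estimators can be scored against it.
* :func:`generate_driver_rasters` — driver layers with a requested
  pairwise correlation structure (Gaussian copula) for collinearity
  screening tests.

Spatial structure is purely block-wise: the downstream methods are
per-cell, so no geostatistical field simulation is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import AlignedStack, RasterGrid

__all__ = [
    "Block", "SyntheticRasterSpec", "LatentModelSpec", "SEMTruth",
    "DRIVER_NAMES", "DRIVER_BLOCKS", "calibrated_quadrant_spec",
    "default_latent_model", "generate_coupled_stacks", "generate_sem_table",
    "generate_driver_rasters", "generate_drivers_from_response",
]

#: The eleven candidate drivers, grouped by latent construct.
DRIVER_BLOCKS: dict[str, list[str]] = {
    "Ter": ["ELE", "SLO"],
    "Hum": ["NL", "PD", "GDP"],
    "Clm": ["PRE", "TEM", "ET"],
    "Veg": ["NPP", "FVC", "kNDVI"],
}
DRIVER_NAMES: list[str] = [d for block in DRIVER_BLOCKS.values() for d in block]

#: Realistic (mean, SD) used to place copula-generated drivers on native scales.
_DRIVER_SCALES = {
    "PRE": (1200.0, 200.0), "TEM": (17.0, 1.5), "ET": (800.0, 150.0),
    "ELE": (200.0, 150.0), "SLO": (5.0, 3.0), "NL": (20.0, 10.0),
    "PD": (500.0, 300.0), "GDP": (3000.0, 1500.0), "NPP": (0.6, 0.15),
    "FVC": (0.6, 0.15), "kNDVI": (0.4, 0.1),
}


# ---------------------------------------------------------------------------
# Coupled HFI/EQI stacks


@dataclass(frozen=True)
class Block:
    """Half-open rectangular block [row0, row1) x [col0, col1) of one class.

    ``trend`` optionally overrides the class-level trend magnitudes for
    this block (same sign conventions apply).
    """

    row0: int
    row1: int
    col0: int
    col1: int
    cls: str
    trend: tuple[float, float] | None = None


@dataclass
class SyntheticRasterSpec:
    """Layout and trend plan for a paired HFI/EQI time series.

    ``trend_magnitudes`` maps each class to its per-epoch-step (signed)
    change in index units as ``(d_hfi, d_eqi)``. Signs must agree with the
    class semantics (coordination +/+, good_for_nature -/+, degradation
    -/-, conflict +/-, insignificant 0/0). Planted trends of significant
    classes must exceed 10% of the analytic change-SD (the mixture of
    block trends plus sampling noise), so the significance rule cannot
    erase them by construction.
    """

    shape: tuple[int, int] = (60, 60)
    epochs: tuple = (2000, 2010, 2020)
    blocks: list[Block] | None = None
    trend_magnitudes: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "coordination": (6.0, 4.0),
        "good_for_nature": (-5.0, 4.0),
        "degradation": (-4.0, -4.0),
        "conflict": (10.0, -5.0),
        "insignificant": (0.0, 0.0),
    })
    base_hfi: float = 35.7
    base_eqi: float = 50.4
    noise_sd: float = 1.0
    nodata_fraction: float = 0.02
    seed: int = 0

    _SIGNS = {
        "coordination": (1, 1), "good_for_nature": (-1, 1),
        "degradation": (-1, -1), "conflict": (1, -1), "insignificant": (0, 0),
    }

    def __post_init__(self) -> None:
        self.shape = tuple(self.shape)
        self.epochs = tuple(self.epochs)
        rows, cols = self.shape
        if rows < 2 or cols < 2:
            raise ValueError("degenerate shape: need at least 2x2 cells")
        if len(self.epochs) < 2:
            raise ValueError("need at least two epochs")
        if not 0 <= self.nodata_fraction < 1:
            raise ValueError("nodata_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.blocks is None:
            # Column strips sized so conflict outweighs coordination ~5:3 and
            # the area-weighted HFI trend is clearly positive, EQI negative.
            fractions = {"coordination": 0.25, "good_for_nature": 0.13,
                         "degradation": 0.12, "conflict": 0.42,
                         "insignificant": 0.08}
            self.blocks = strip_layout(self.shape, fractions)
        self._check_tiling()
        sigmas = self.change_sigmas()
        for b in self.blocks:
            dh, de = self.block_trend(b)
            sh, se = self._SIGNS[b.cls]
            if np.sign(dh) != sh or np.sign(de) != se:
                raise ValueError(f"trend signs for {b.cls!r} contradict its quadrant")
            if b.cls != "insignificant":
                for axis, name in ((0, "HFI"), (1, "EQI")):
                    mag = (dh, de)[axis]
                    if abs(mag) <= 0.1 * sigmas[axis] - 1e-12:
                        raise ValueError(
                            f"{b.cls} {name} trend {mag} does not exceed 10% "
                            f"of the analytic change-SD {sigmas[axis]:.3f}")

    def _check_tiling(self) -> None:
        cover = np.zeros(self.shape, dtype=int)
        for b in self.blocks:
            if b.cls not in self._SIGNS:
                raise ValueError(f"unknown class {b.cls!r}")
            cover[b.row0:b.row1, b.col0:b.col1] += 1
        if cover.max() > 1:
            raise ValueError("blocks overlap")
        if cover.min() < 1:
            raise ValueError("blocks do not tile the grid")

    def block_trend(self, block: Block) -> tuple[float, float]:
        """Effective per-step (dHFI, dEQI) trend of one block."""
        return block.trend if block.trend is not None else tuple(
            self.trend_magnitudes[block.cls])

    def class_map(self) -> np.ndarray:
        """Object array of planted class names per cell."""
        out = np.empty(self.shape, dtype=object)
        for b in self.blocks:
            out[b.row0:b.row1, b.col0:b.col1] = b.cls
        return out

    def change_sigmas(self) -> tuple[float, float]:
        """Analytic SD of the one-step change rasters (block mixture + noise).

        Each cell's change is its block trend plus the difference of two
        independent noise draws, so the change variance is the variance of
        the block-trend mixture plus 2 * noise_sd**2.
        """
        areas = np.array([(b.row1 - b.row0) * (b.col1 - b.col0) for b in self.blocks], float)
        w = areas / areas.sum()
        trends = np.array([self.block_trend(b) for b in self.blocks])
        sig = []
        for axis in (0, 1):
            mu = trends[:, axis]
            mix_var = np.sum(w * mu**2) - np.sum(w * mu) ** 2
            sig.append(float(np.sqrt(mix_var + 2.0 * self.noise_sd**2)))
        return sig[0], sig[1]


def calibrated_quadrant_spec(noise_sd: float = 0.3, factor: float = 3.0,
                             seed: int = 0, shape: tuple[int, int] = (60, 60),
                             ) -> SyntheticRasterSpec:
    """Spec whose weakest planted trends sit at ``factor`` x the significance threshold.

    Four large-trend anchor blocks pin the change-SD of each axis; two
    further blocks carry trends iterated to exactly ``factor`` times the
    10%-of-SD significance threshold, and one block is planted as
    insignificant (zero trend). Used to probe the classifier's error rate
    right at a stated multiple of its own decision boundary.
    """
    rows, cols = shape
    anchors = {"coordination": (10.0, 8.0), "good_for_nature": (-10.0, 8.0),
               "degradation": (-10.0, -8.0), "conflict": (10.0, -8.0)}

    def build(weak_h: float, weak_e: float) -> SyntheticRasterSpec:
        # 4 anchor strips (60% of columns), 2 weak strips (30%), 1 zero strip.
        fracs = [0.15, 0.15, 0.15, 0.15, 0.15, 0.15, 0.10]
        edges = np.round(np.cumsum([0] + fracs) * cols).astype(int)
        edges[-1] = cols
        classes = list(anchors) + ["coordination", "conflict", "insignificant"]
        blocks = []
        for i, (cls, c0, c1) in enumerate(zip(classes, edges[:-1], edges[1:])):
            if i < 4:
                trend = anchors[cls]
            elif cls == "coordination":
                trend = (weak_h, weak_e)
            elif cls == "conflict":
                trend = (weak_h, -weak_e)
            else:
                trend = (0.0, 0.0)
            blocks.append(Block(0, rows, int(c0), int(c1), cls, trend=trend))
        return SyntheticRasterSpec(shape=shape, blocks=blocks, noise_sd=noise_sd,
                                   nodata_fraction=0.0, seed=seed)

    weak_h, weak_e = 2.0, 2.0
    for _ in range(25):  # fixed-point iteration on the realized change-SD
        spec = build(weak_h, weak_e)
        sig_h, sig_e = spec.change_sigmas()
        new_h, new_e = factor * 0.1 * sig_h, factor * 0.1 * sig_e
        if abs(new_h - weak_h) < 1e-10 and abs(new_e - weak_e) < 1e-10:
            break
        weak_h, weak_e = new_h, new_e
    return build(weak_h, weak_e)


def strip_layout(shape: tuple[int, int], fractions: Mapping[str, float]) -> list[Block]:
    """Vertical column strips with widths proportional to ``fractions``."""
    rows, cols = shape
    edges = np.round(np.cumsum([0.0] + list(fractions.values())) * cols).astype(int)
    edges[-1] = cols
    return [Block(0, rows, int(c0), int(c1), cls)
            for cls, c0, c1 in zip(fractions, edges[:-1], edges[1:]) if c1 > c0]


def generate_coupled_stacks(spec: SyntheticRasterSpec) -> tuple[AlignedStack, AlignedStack]:
    """Paired HFI-like and EQI-like stacks with planted block trends.

    Bit-identical output for identical spec + seed; the nodata mask is
    shared across epochs and between the two stacks.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    n_ep = len(spec.epochs)
    mask = rng.random(spec.shape) < spec.nodata_fraction

    trend_h = np.zeros(spec.shape)
    trend_e = np.zeros(spec.shape)
    for b in spec.blocks:
        dh, de = spec.block_trend(b)
        trend_h[b.row0:b.row1, b.col0:b.col1] = dh
        trend_e[b.row0:b.row1, b.col0:b.col1] = de

    def build(base: float, trend: np.ndarray) -> AlignedStack:
        grids = []
        for step, epoch in enumerate(spec.epochs):
            vals = base + step * trend + rng.normal(0.0, spec.noise_sd, spec.shape)
            grids.append(RasterGrid(np.clip(vals, 0.0, 100.0), mask=mask.copy(), epoch=epoch))
        return AlignedStack(grids)

    return build(spec.base_hfi, trend_h), build(spec.base_eqi, trend_e)


# ---------------------------------------------------------------------------
# Latent path model tables


@dataclass
class LatentModelSpec:
    """Generative latent path model (recursive/acyclic, reflective blocks).

    ``path_matrix`` is strictly lower-triangular in the order of
    ``latent_names``: row j holds the structural coefficients of latent j
    on its predecessors. Exogenous latents are standard normal; endogenous
    latent j is the coefficient-weighted sum of its predecessors plus
    Gaussian noise of SD ``structural_noise_sd[j]``. Indicators are
    loading x latent + Gaussian measurement noise.
    """

    latent_names: list[str]
    path_matrix: np.ndarray
    blocks: Mapping[str, list[str]]
    loadings: Mapping[str, float]
    structural_noise_sd: Mapping[str, float]
    measurement_noise_sd: Mapping[str, float]
    n: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        self.path_matrix = np.asarray(self.path_matrix, dtype=float)
        p = len(self.latent_names)
        if self.path_matrix.shape != (p, p):
            raise ValueError("path_matrix shape must match latent_names")
        if np.any(np.triu(self.path_matrix) != 0):
            raise ValueError("path_matrix must be strictly lower-triangular "
                             "(acyclic in the latent order)")
        seen: set[str] = set()
        for latent, inds in self.blocks.items():
            if latent not in self.latent_names:
                raise ValueError(f"block for unknown latent {latent!r}")
            dup = seen.intersection(inds)
            if dup:
                raise ValueError(f"indicators in more than one block: {sorted(dup)}")
            seen.update(inds)
        for ind in seen:
            if self.loadings.get(ind, 0.0) == 0.0:
                raise ValueError(f"indicator {ind!r} needs a non-zero loading")
        n_ind = sum(len(v) for v in self.blocks.values())
        if self.n < 10 * n_ind:
            raise ValueError(f"n must be at least 10x the {n_ind} indicators")

    @classmethod
    def standardized(cls, latent_names: Sequence[str], paths: Mapping[tuple[str, str], float],
                     blocks: Mapping[str, list[str]], loadings: Mapping[str, float],
                     n: int = 2000, seed: int = 0) -> "LatentModelSpec":
        """Spec in which paths and loadings ARE the standardized truth.

        Noise SDs are derived so every latent and indicator has unit
        variance, making ``paths`` the standardized structural coefficients
        and ``loadings`` the indicator-latent correlations. Raises if the
        requested coefficients are infeasible (implied noise variance < 0).
        """
        p = len(latent_names)
        idx = {name: i for i, name in enumerate(latent_names)}
        B = np.zeros((p, p))
        for (src, dst), val in paths.items():
            i, j = idx[dst], idx[src]
            if j >= i:
                raise ValueError(f"path {src}->{dst} violates the latent order")
            B[i, j] = val
        # Build the unit-variance latent covariance recursively.
        sigma = np.eye(p)
        znoise: dict[str, float] = {}
        for i in range(p):
            b = B[i, :i]
            explained = float(b @ sigma[:i, :i] @ b) if b.size else 0.0
            resid = 1.0 - explained
            if resid < 0:
                raise ValueError(f"paths into {latent_names[i]} imply variance > 1")
            znoise[latent_names[i]] = float(np.sqrt(resid))
            cov = sigma[:i, :i] @ b if i else np.zeros(0)
            sigma[i, :i] = cov
            sigma[:i, i] = cov
        meas = {}
        for latent, inds in blocks.items():
            for ind in inds:
                lam = loadings[ind]
                if abs(lam) > 1:
                    raise ValueError(f"standardized loading |{lam}| > 1 for {ind}")
                meas[ind] = float(np.sqrt(max(1.0 - lam**2, 0.0)))
        return cls(list(latent_names), B, dict(blocks), dict(loadings),
                   znoise, meas, n=n, seed=seed)

    def latent_cov(self) -> np.ndarray:
        """Population covariance of the latents implied by the recursion."""
        p = len(self.latent_names)
        psi = np.zeros(p)
        for i, name in enumerate(self.latent_names):
            if self.path_matrix[i].any():
                psi[i] = self.structural_noise_sd.get(name, 0.0) ** 2
            else:
                psi[i] = 1.0  # exogenous latents are standard normal
        inv = np.linalg.inv(np.eye(p) - self.path_matrix)
        return inv @ np.diag(psi) @ inv.T


@dataclass
class SEMTruth:
    """Analytic standardized parameters of a generating latent model."""

    paths: pd.DataFrame          # rows = target latent, cols = source latent
    loadings: dict[str, float]   # indicator -> standardized loading
    latent_corr: pd.DataFrame


def _standardized_truth(spec: LatentModelSpec) -> SEMTruth:
    cov = spec.latent_cov()
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    B_std = spec.path_matrix * sd[np.newaxis, :] / sd[:, np.newaxis]
    names = spec.latent_names
    lat_sd = dict(zip(names, sd))
    load_std = {}
    for latent, inds in spec.blocks.items():
        for ind in inds:
            lam, eps = spec.loadings[ind], spec.measurement_noise_sd.get(ind, 0.0)
            s_lat = lat_sd[latent]
            s_ind = np.sqrt((lam * s_lat) ** 2 + eps**2)
            load_std[ind] = float(lam * s_lat / s_ind)
    return SEMTruth(pd.DataFrame(B_std, index=names, columns=names),
                    load_std,
                    pd.DataFrame(corr, index=names, columns=names))


def generate_sem_table(spec: LatentModelSpec) -> tuple[pd.DataFrame, SEMTruth]:
    """Simulate an indicator table from the latent model.

    Returns the table (indicator columns, standardized to sample mean 0 /
    SD 1) and the analytic standardized truth for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    p = len(spec.latent_names)
    latents = np.zeros((spec.n, p))
    for i, name in enumerate(spec.latent_names):
        b = spec.path_matrix[i, :i]
        if b.any():
            mean = latents[:, :i] @ b
            latents[:, i] = mean + rng.normal(0.0, spec.structural_noise_sd.get(name, 0.0), spec.n)
        else:
            latents[:, i] = rng.normal(0.0, 1.0, spec.n)
    data = {}
    for latent, inds in spec.blocks.items():
        z = latents[:, spec.latent_names.index(latent)]
        for ind in inds:
            x = spec.loadings[ind] * z + rng.normal(
                0.0, spec.measurement_noise_sd.get(ind, 0.0), spec.n)
            data[ind] = (x - x.mean()) / x.std()
    table = pd.DataFrame(data)
    return table, _standardized_truth(spec)


#: Standardized true paths used by the default driving-mechanism fixture:
#: terrain constrains human activity and supports vegetation; human
#: activity warms/perturbs climate and suppresses vegetation; vegetation
#: is the strongest positive driver of coordination.
DEFAULT_TRUE_PATHS: dict[tuple[str, str], float] = {
    ("Ter", "Hum"): -0.35, ("Ter", "Veg"): 0.30, ("Ter", "CCD"): -0.30,
    ("Hum", "Clm"): 0.40, ("Hum", "Veg"): -0.30, ("Hum", "CCD"): 0.35,
    ("Clm", "Veg"): -0.25, ("Clm", "CCD"): -0.20,
    ("Veg", "CCD"): 0.50,
}

#: Standardized loadings echoing realistic indicator reliabilities.
DEFAULT_LOADINGS: dict[str, float] = {
    "ELE": 0.92, "SLO": 0.90, "NL": 0.85, "PD": 0.75, "GDP": 0.70,
    "PRE": 0.73, "TEM": 0.55, "ET": 0.85, "NPP": 0.90, "FVC": 0.94,
    "kNDVI": 0.60, "CCD": 1.0,
}


def default_latent_model(n: int = 2000, seed: int = 0,
                         paths: Mapping[tuple[str, str], float] | None = None,
                         loadings: Mapping[str, float] | None = None) -> LatentModelSpec:
    """The four-construct driving-mechanism model with a single-indicator CCD block."""
    blocks = {**{k: list(v) for k, v in DRIVER_BLOCKS.items()}, "CCD": ["CCD"]}
    return LatentModelSpec.standardized(
        ["Ter", "Hum", "Clm", "Veg", "CCD"],
        dict(paths if paths is not None else DEFAULT_TRUE_PATHS),
        blocks,
        dict(loadings if loadings is not None else DEFAULT_LOADINGS),
        n=n, seed=seed)


# ---------------------------------------------------------------------------
# Driver rasters


def generate_driver_rasters(shape: tuple[int, int],
                            collinearity_pairs: Mapping[tuple[str, str], float] | None = None,
                            seed: int = 0,
                            names: Sequence[str] = tuple(DRIVER_NAMES),
                            ) -> dict[str, RasterGrid]:
    """Driver layers with a planted pairwise correlation structure.

    A Gaussian copula: multivariate normal scores with the requested
    correlation matrix, placed on each driver's native scale by an affine
    map (which preserves the correlations). Deterministic for a seed.
    """
    names = list(names)
    k = len(names)
    corr = np.eye(k)
    for (a, b), r in (collinearity_pairs or {}).items():
        if not -1 < r < 1:
            raise ValueError(f"requested correlation {r} for ({a}, {b}) not in (-1, 1)")
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = r
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError("requested correlation matrix is not positive semi-definite")
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((shape[0] * shape[1], k)) @ L.T
    out = {}
    for i, name in enumerate(names):
        mu, sd = _DRIVER_SCALES.get(name, (0.0, 1.0))
        out[name] = RasterGrid((mu + sd * z[:, i]).reshape(shape))
    return out


def generate_drivers_from_response(response: np.ndarray, spec: LatentModelSpec,
                                   seed: int = 0,
                                   response_latent: str = "CCD") -> pd.DataFrame:
    """Driver indicators consistent with an observed response series.

    Treats the standardized ``response`` as the realised score of the
    response latent and samples the remaining latents from their Gaussian
    conditional distribution given it, then emits indicators with the
    spec's loadings and measurement noise. Cross-covariances between the
    drivers and the response match the latent model exactly when the
    response is standardized, whatever its marginal shape — which is what
    covariance-based estimators see.
    """
    rng = np.random.default_rng(seed)
    z = np.asarray(response, dtype=float)
    z = (z - z.mean()) / z.std()
    names = spec.latent_names
    r = names.index(response_latent)
    others = [i for i in range(len(names)) if i != r]
    cov = spec.latent_cov()
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    c = corr[np.ix_(others, [r])]            # cross-correlations with response
    cond_cov = corr[np.ix_(others, others)] - c @ c.T
    # Guard tiny negative eigenvalues from finite arithmetic.
    w, V = np.linalg.eigh(cond_cov)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    eps = rng.standard_normal((z.size, len(others)))
    lat = np.empty((z.size, len(names)))
    lat[:, others] = z[:, None] * c.T + eps @ root.T
    lat[:, r] = z
    truth = _standardized_truth(spec)
    data = {}
    for latent, inds in spec.blocks.items():
        if latent == response_latent:
            continue
        col = lat[:, names.index(latent)]
        for ind in inds:
            lam_std = truth.loadings[ind]
            x = lam_std * col + rng.normal(0.0, np.sqrt(max(1 - lam_std**2, 0.0)), z.size)
            data[ind] = x
    return pd.DataFrame(data)
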