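"""End-to-end orchestration: indices -> quadrants -> CCD -> screening -> PLS.

One :class:`RunConfig` drives the whole grid-scale analysis:

1. load (or synthesise) aligned HFI and EQI stacks on a 0-100 scale;
2. min-max rescale both to [0, 1] over the pooled epochs;
3. classify each consecutive period and the union period into the
   four-quadrant evolution types;
4. compute C / T / CCD and the five coordination levels per epoch;
5. for each region class present in the union-period quadrant map, build
   a per-cell driver table, screen drivers (VIF x permutation
   importance), and fit the PLS path model on the surviving indicators,
   with optional bootstrap inference.

Every stage is seeded from the config's global seed, so identical
config + seed reproduces identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import coupling, indices, plspm, quadrant, screening
from .raster import AlignedStack, RasterGrid, read_raster, write_raster
from .synthetic import (LatentModelSpec, SyntheticRasterSpec, default_latent_model,
                        generate_coupled_stacks, generate_drivers_from_response)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "zonal_summary"]

log = logging.getLogger("ecocouple.pipeline")

_CSV_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``layers`` names input rasters per epoch (keys ``hfi`` and
    ``eqi``, each a mapping epoch -> file path), or ``synthetic_spec``
    asks for generated inputs with planted truth. In synthetic mode the
    driver tables are simulated from ``latent_model`` conditionally on
    the computed CCD, so the structural truth is known.
    """

    out_dir: Path | None = None
    seed: int = 0
    layers: Mapping[str, Mapping[int, str]] | None = None
    synthetic_spec: SyntheticRasterSpec | None = None
    latent_model: LatentModelSpec | None = None
    sigma_fraction: float = 0.1
    significance: str = "or"
    ccd_params: coupling.CCDParams = field(default_factory=coupling.CCDParams)
    pls_spec: plspm.PathModelSpec | None = None
    regions: tuple[str, ...] = ("coordination", "good_for_nature",
                                "degradation", "conflict")
    vif_threshold: float = 6.0
    n_trees: int = 500
    n_permutations: int = 100
    alpha: float = 0.05
    bootstrap_B: int = 0          # 0 skips bootstrap inference
    min_region_rows: int = 120
    max_region_rows: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw:
            raw["synthetic_spec"] = SyntheticRasterSpec(**raw.pop("synthetic"))
        if "ccd" in raw:
            raw["ccd_params"] = coupling.CCDParams(**raw.pop("ccd"))
        if "out_dir" in raw and raw["out_dir"] is not None:
            raw["out_dir"] = Path(raw["out_dir"])
        if "regions" in raw:
            raw["regions"] = tuple(raw["regions"])
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the configuration for provenance."""
        def default(o):
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return {k: v for k, v in vars(o).items() if not k.startswith("_")}
            return repr(o)

        blob = json.dumps(vars(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything a run produced, stage by stage."""

    quadrant_proportions: dict[str, pd.Series]
    ccd_proportions: dict[int, pd.Series]
    hfi_means: dict[int, float]
    eqi_means: dict[int, float]
    screening: dict[str, screening.ScreeningReport]
    pls: dict[str, plspm.PLSFit]
    pls_effects: dict[str, plspm.EffectsTable]
    pls_bootstrap: dict[str, "plspm.BootstrapResult"]
    warnings: list[str]
    provenance: dict
    outputs: list[str]


def _load_stack(layer: Mapping[int, str]) -> AlignedStack:
    return AlignedStack([read_raster(path, epoch=epoch)
                         for epoch, path in sorted(layer.items())])


def zonal_summary(grid: RasterGrid, zones: RasterGrid) -> pd.DataFrame:
    """Per-zone mean, SD and count of a grid over unmasked cells."""
    grid.require_aligned(zones, "zones")
    valid = ~(grid.mask | zones.mask)
    if not valid.any():
        log.warning("zonal_summary: no overlapping unmasked cells")
        return pd.DataFrame(columns=["mean", "sd", "count"])
    df = pd.DataFrame({"zone": zones.values[valid], "value": grid.values[valid]})
    out = df.groupby("zone")["value"].agg(mean="mean", sd=lambda v: v.std(ddof=0),
                                          count="count")
    out["count"] = out["count"].astype(int)
    return out


def _prune_pls_spec(spec: plspm.PathModelSpec, selected: list[str],
                    response_latent: str = "CCD") -> tuple[plspm.PathModelSpec, list[str]]:
    """Drop unselected indicators and latents left without indicators."""
    warnings_: list[str] = []
    blocks = {}
    for latent, inds in spec.blocks.items():
        keep = inds if latent == response_latent else [c for c in inds if c in selected]
        if keep:
            blocks[latent] = keep
        else:
            warnings_.append(f"latent {latent} dropped: no surviving indicator")
    names = [n for n in spec.latent_names if n in blocks]
    edges = [(s, d) for s, d in spec.edges if s in blocks and d in blocks]
    return (plspm.PathModelSpec(names, blocks, edges, inner_scheme=spec.inner_scheme,
                                max_iter=spec.max_iter, tol=spec.tol), warnings_)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``."""
    rng = np.random.default_rng(config.seed)
    warnings_: list[str] = []
    outputs: list[str] = []
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def save_csv(df, name: str) -> None:
        if out_dir is None:
            return
        path = out_dir / name
        (df.to_frame() if isinstance(df, pd.Series) else df).to_csv(
            path, float_format=_CSV_FMT)
        outputs.append(name)

    # Stage 1: inputs -----------------------------------------------------
    if config.synthetic_spec is not None:
        spec = config.synthetic_spec
        hfi, eqi = generate_coupled_stacks(spec)
    elif config.layers is not None:
        hfi = _load_stack(config.layers["hfi"])
        eqi = _load_stack(config.layers["eqi"])
        hfi.grids[0].require_aligned(eqi.grids[0], "eqi layer")
    else:
        raise ValueError("config needs either layers or a synthetic_spec")
    epochs = hfi.epochs
    log.info("inputs: %d epochs, %d valid cells", len(epochs), int((~hfi.mask).sum()))
    hfi_means = {e: float(hfi.grid(e).unmasked().mean()) for e in epochs}
    eqi_means = {e: float(eqi.grid(e).unmasked().mean()) for e in epochs}

    # Stage 2: quadrant maps ----------------------------------------------
    periods = [(a, b) for a, b in zip(epochs[:-1], epochs[1:])]
    union_period = (epochs[0], epochs[-1])
    if union_period not in periods:
        periods.append(union_period)
    quad_props: dict[str, pd.Series] = {}
    quad_maps: dict[tuple, quadrant.QuadrantMap] = {}
    for t0, t1 in periods:
        change = quadrant.period_change(hfi, eqi, t0, t1)
        qmap = quadrant.classify_quadrant(change, config.sigma_fraction,
                                          config.significance)  # type: ignore[arg-type]
        quad_maps[(t0, t1)] = qmap
        props = quadrant.area_proportions(qmap)
        quad_props[f"{t0}-{t1}"] = props
        save_csv(props, f"quadrant_proportions_{t0}_{t1}.csv")
    region_map = quad_maps[union_period]

    # Stage 3: CCD ---------------------------------------------------------
    hfi01 = indices.minmax_normalize(hfi, 0.0, 1.0, "pooled-epochs")
    eqi01 = indices.minmax_normalize(eqi, 0.0, 1.0, "pooled-epochs")
    ccd_props: dict[int, pd.Series] = {}
    ccd_results: dict[int, coupling.CCDResult] = {}
    for e in epochs:
        res = coupling.ccd_pipeline(hfi01.grid(e), eqi01.grid(e), config.ccd_params)
        ccd_results[e] = res
        ccd_props[e] = res.proportions
        save_csv(res.proportions, f"ccd_levels_{e}.csv")
        if out_dir:
            write_raster(res.ccd, out_dir / f"ccd_{e}.asc")
            outputs.append(f"ccd_{e}.asc")

    # Stage 4: region-stratified screening + PLS ---------------------------
    analysis_epoch = epochs[-1]
    ccd_grid = ccd_results[analysis_epoch].ccd
    pls_spec = config.pls_spec or plspm.default_path_model()
    latent_model = config.latent_model or default_latent_model()
    screen_reports: dict[str, screening.ScreeningReport] = {}
    pls_fits: dict[str, plspm.PLSFit] = {}
    pls_eff: dict[str, plspm.EffectsTable] = {}
    pls_boot: dict[str, plspm.BootstrapResult] = {}
    for region in config.regions:
        rmask = region_map.region_mask(region) & ~ccd_grid.mask
        n_cells = int(rmask.sum())
        if n_cells < config.min_region_rows:
            warnings_.append(f"region {region} skipped: {n_cells} cells "
                             f"< {config.min_region_rows}")
            continue
        response = ccd_grid.values[rmask]
        if config.max_region_rows and n_cells > config.max_region_rows:
            pick = rng.choice(n_cells, config.max_region_rows, replace=False)
            response = response[np.sort(pick)]
        region_seed = int(rng.integers(2**31 - 1))
        if config.synthetic_spec is not None:
            table = generate_drivers_from_response(response, latent_model,
                                                   seed=region_seed)
        else:
            driver_layers = {name: _load_stack(layer).grid(analysis_epoch)
                             for name, layer in config.layers.items()
                             if name not in ("hfi", "eqi", "lai", "gpp", "evi")}
            if not driver_layers:
                warnings_.append(f"region {region}: no driver layers configured")
                continue
            table = pd.DataFrame({name: g.values[rmask]
                                  for name, g in driver_layers.items()})
        table["CCD"] = (response - response.mean()) / (response.std() or 1.0)
        table["region"] = region
        log.info("region %s: %d rows", region, len(table))

        rep = screening.screen_drivers(
            table, response="CCD",
            predictors=[c for c in table.columns if c not in ("CCD", "region")],
            vif_threshold=config.vif_threshold, n_trees=config.n_trees,
            n_permutations=config.n_permutations, alpha=config.alpha,
            seed=region_seed)
        screen_reports[region] = rep
        warnings_.extend(f"{region}: {w}" for w in rep.warnings)
        save_csv(pd.DataFrame({"vif": rep.vif, "inc_mse": rep.importance,
                               "p": rep.importance_p}),
                 f"screening_{region}_{analysis_epoch}.csv")
        if not rep.selected:
            warnings_.append(f"region {region}: PLS skipped (no driver selected)")
            continue
        sub_spec, prune_warn = _prune_pls_spec(pls_spec, rep.selected)
        warnings_.extend(f"{region}: {w}" for w in prune_warn)
        try:
            fit = plspm.fit_pls_pm(table, sub_spec)
        except ValueError as exc:
            warnings_.append(f"region {region}: PLS failed ({exc})")
            continue
        pls_fits[region] = fit
        pls_eff[region] = plspm.effects(fit)
        save_csv(fit.path_coefficients, f"paths_{region}_{analysis_epoch}.csv")
        save_csv(pls_eff[region].table.set_index(["source", "target"]),
                 f"effects_{region}_{analysis_epoch}.csv")
        if config.bootstrap_B:
            boot = plspm.bootstrap_inference(table, sub_spec, B=config.bootstrap_B,
                                             seed=region_seed, base_fit=fit)
            pls_boot[region] = boot
            save_csv(boot.table.set_index(["source", "target"]),
                     f"bootstrap_{region}_{analysis_epoch}.csv")

    provenance = {"config_hash": config.digest(), "seed": config.seed,
                  "epochs": list(epochs), "analysis_epoch": analysis_epoch,
                  "outputs": outputs}
    report = RunReport(quad_props, ccd_props, hfi_means, eqi_means,
                       screen_reports, pls_fits, pls_eff, pls_boot,
                       warnings_, provenance, outputs)
    if out_dir:
        summary = {
            "provenance": provenance,
            "hfi_means": hfi_means, "eqi_means": eqi_means,
            "quadrant_proportions": {k: v.to_dict() for k, v in quad_props.items()},
            "ccd_levels": {str(k): v.to_dict() for k, v in ccd_props.items()},
            "selected_drivers": {r: rep.selected for r, rep in screen_reports.items()},
            "gof": {r: {"value": f.gof, "label": f.gof_label}
                    for r, f in pls_fits.items()},
            "warnings": warnings_,
        }
        (out_dir / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        outputs.append("report.json")
    return report
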