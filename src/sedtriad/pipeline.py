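"""End-to-end orchestration: chemistry -> EC50 -> IBR -> integration.

`run_pipeline` reads the validated CSV inputs, runs every stage of the
assessment and writes a report bundle:

* ``sqgq.csv`` — per-site SQG-Q indices and impact classes;
* ``ec50.csv`` — EC50 point estimates with 95% CIs per site x fraction
  x endpoint x FPG flag ("-" where non-estimable);
* ``ibr.json`` / ``ibr_scores.csv`` / ``star_coordinates.csv`` — the
  IBR decomposition;
* ``loe_matrix.csv``, ``loe_normalized.csv``, ``sites.nwk``,
  ``endpoints.nwk`` — the integrated matrix and both dendrograms;
* ``surface_<endpoint>.asc`` — IDW rasters when coordinates are given;
* ``run_log.json`` — seed, options and stage record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_mod
from .datasets import SITE_AREA
from .doseresponse import DoseResponseSeries, estimate_ec50, normalize_genotoxicity
from .exceptions import SedtriadError
from .ibr import global_ibr
from .integrate import (SpatialField, ec50_to_potency, idw_interpolate,
                        site_cluster_pipeline, surface_to_ascii_grid)
from .sqgq import GuidelineTable, SedimentChemistry, sqgq_table

logger = logging.getLogger(__name__)


class PipelineStageError(SedtriadError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and options for a full run; unset inputs skip their stage."""

    chemistry: str | Path | None = None
    guidelines: str | Path | None = None      # None -> bundled marine PELs
    dose_response: str | Path | None = None
    biomarkers: str | Path | None = None       # per-individual or panel CSV
    coordinates: str | Path | None = None
    out_dir: str | Path = "sedtriad_out"
    site_area: dict = field(default_factory=lambda: dict(SITE_AREA))
    ibr_method: str = "pooled_total"
    ibr_directions: dict | None = None
    max_tail: float | None = None              # None -> study maximum from data
    idw_power: float = 2.0
    grid_resolution: tuple = (50, 50)
    seed: int | None = None

    def validate(self):
        for name in ("chemistry", "guidelines", "dose_response", "biomarkers",
                     "coordinates"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise PipelineStageError("config", f"input file not found: {path}")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc
        return wrapper
    return deco


@_stage("sqgq")
def _run_sqgq(config: PipelineConfig, out: Path) -> pd.DataFrame | None:
    if config.chemistry is None:
        return None
    frame = io_mod.validate_schema(config.chemistry, "chemistry")
    guidelines = (GuidelineTable.from_csv(config.guidelines)
                  if config.guidelines else GuidelineTable.default_marine_pel())
    table = sqgq_table(SedimentChemistry.from_frame(frame), guidelines)
    table.to_csv(out / "sqgq.csv", index=False)
    return table


@_stage("ec50")
def _run_ec50(config: PipelineConfig, out: Path) -> pd.DataFrame | None:
    if config.dose_response is None:
        return None
    frame = io_mod.validate_schema(config.dose_response, "dose_response")
    rows = []
    tail = frame[frame["endpoint"] == "tail_pct"]
    max_tail = config.max_tail
    if max_tail is None and len(tail):
        max_tail = float(tail["response"].max())
    for (site, fraction, endpoint, fpg), grp in frame.groupby(
            ["site", "fraction", "endpoint", "fpg"], sort=True):
        obs = grp[["concentration", "replicate", "response"]].copy()
        if endpoint == "tail_pct":
            obs["response"] = normalize_genotoxicity(obs["response"].to_numpy(),
                                                     max_tail)
        series = DoseResponseSeries(site=site, fraction=int(fraction),
                                    endpoint=endpoint, fpg=bool(fpg),
                                    observations=obs)
        est = estimate_ec50(series)
        rows.append({
            "site": site, "fraction": int(fraction), "endpoint": endpoint,
            "fpg": bool(fpg),
            "ec50": est.point if est.estimable else np.nan,
            "ci_low": est.ci95[0] if est.estimable else np.nan,
            "ci_high": est.ci95[1] if est.estimable else np.nan,
            "estimable": est.estimable,
            "rendered": est.render(),
        })
    table = pd.DataFrame(rows)
    table.to_csv(out / "ec50.csv", index=False)
    return table


@_stage("ibr")
def _run_ibr(config: PipelineConfig, out: Path):
    if config.biomarkers is None:
        return None
    raw = pd.read_csv(config.biomarkers)
    if "value" in raw.columns:  # per-individual rows: aggregate first
        from .simulate import aggregate_biomarkers
        io_mod.validate_schema(raw, "biomarkers")
        panel = aggregate_biomarkers(raw)
    else:
        panel = io_mod.validate_schema(raw, "biomarker_panel")
    result = global_ibr(panel, directions=config.ibr_directions,
                        method=config.ibr_method)
    result.scores.to_csv(out / "ibr_scores.csv")
    result.star_coordinates.to_csv(out / "star_coordinates.csv", index=False)
    payload = {
        "ibr": result.ibr.to_dict(),
        "species_scores": {sp: row.to_dict()
                           for sp, row in result.species_scores.iterrows()},
        "star_order": list(result.scores.index),
    }
    (out / "ibr.json").write_text(json.dumps(payload, indent=2))
    return result


@_stage("integrate")
def _run_integrate(config: PipelineConfig, out: Path, sqgq_table_df, ec50_table,
                   ibr_result):
    pieces = {}
    if sqgq_table_df is not None:
        sq = sqgq_table_df.set_index("site")
        for col in ("sqgq_total", "sqgq_metal", "sqgq_organic"):
            if col in sq.columns:
                pieces[col] = sq[col]
    if ec50_table is not None:
        tail = ec50_table[ec50_table["endpoint"] == "tail_pct"]
        for (fraction, fpg), grp in tail.groupby(["fraction", "fpg"]):
            name = f"potency_{'oxsb' if fpg else 'sb'}_f{fraction}"
            ec = grp.set_index("site")["ec50"]
            pieces[name] = pd.Series(ec50_to_potency(ec.to_numpy()), index=ec.index)
    if ibr_result is not None and pieces:
        sites = next(iter(pieces.values())).index
        mapped = {}
        for site in sites:
            area = config.site_area.get(site, site)
            if area in ibr_result.ibr.index:
                mapped[site] = float(ibr_result.ibr[area])
        if mapped:
            pieces["ibr_ox"] = pd.Series(mapped)
    if len(pieces) < 2:
        logger.info("fewer than 2 endpoints available; integration skipped")
        return None
    matrix = pd.DataFrame(pieces)
    matrix.index.name = "site"
    matrix.to_csv(out / "loe_matrix.csv")
    result = site_cluster_pipeline(matrix)
    result.normalized.to_csv(out / "loe_normalized.csv")
    (out / "sites.nwk").write_text(result.site_newick + "\n")
    (out / "endpoints.nwk").write_text(result.endpoint_newick + "\n")

    if config.coordinates is not None:
        coords = io_mod.validate_schema(config.coordinates, "coordinates")
        pts = coords[coords["site"].isin(result.normalized.index)]
        if len(pts) >= 1:
            pad_x = 0.1 * (pts["x"].max() - pts["x"].min() or 1.0)
            pad_y = 0.1 * (pts["y"].max() - pts["y"].min() or 1.0)
            bbox = (pts["x"].min() - pad_x, pts["x"].max() + pad_x,
                    pts["y"].min() - pad_y, pts["y"].max() + pad_y)
            for endpoint in result.normalized.columns:
                values = result.normalized.loc[pts["site"], endpoint]
                surf = idw_interpolate(
                    SpatialField(points=pts, values=values, bbox=bbox,
                                 resolution=config.grid_resolution),
                    power=config.idw_power)
                fname = out / f"surface_{endpoint}.asc"
                fname.write_text(surface_to_ascii_grid(surf, bbox))
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Returns the in-memory stage results keyed by stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sqgq_df = _run_sqgq(config, out)
    ec50_df = _run_ec50(config, out)
    ibr_res = _run_ibr(config, out)
    integ = _run_integrate(config, out, sqgq_df, ec50_df, ibr_res)

    import sedtriad
    log = {
        "seed": config.seed,
        "version": sedtriad.__version__,
        "stages": {
            "sqgq": sqgq_df is not None,
            "ec50": ec50_df is not None,
            "ibr": ibr_res is not None,
            "integrate": integ is not None,
        },
        "options": {
            "ibr_method": config.ibr_method,
            "idw_power": config.idw_power,
            "max_tail": config.max_tail,
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"sqgq": sqgq_df, "ec50": ec50_df, "ibr": ibr_res, "integrate": integ}
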