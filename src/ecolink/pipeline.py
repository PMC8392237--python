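"""End-to-end pipeline: synthetic landscape → services → sensitivity →
sources → resistance → corridors → circuit analysis → barriers/pinch points
→ report.

The pipeline is configured by a single :class:`PipelineConfig` (YAML on
disk), is fully deterministic under a fixed seed, and writes plain-text
artifacts: ESRI ASCII rasters, GeoJSON vectors, CSV tables and a JSON run
manifest recording the config hash, seed, package versions and per-stage
summary statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, landcover
from .grid import (
    RasterGrid, connected_patches, euclidean_distance, rasterize_lines,
    rasterize_points, rasterize_polygons, relief, slope, write_ascii_grid,
)
from .synthetic import LandscapeBundle, LandscapeConfig, generate, make_fixture
from .services import (
    default_carbon_pools, default_habitat_params, default_threats,
    degradation, habitat_quality, water_yield, carbon_storage, integrated_services,
)
from .sensitivity import (
    CSLEFactors, csle, habitat_sensitivity, integrated_sensitivity,
    ls_factor, water_sensitivity,
)
from .sources import SourcePatch, ecological_importance, select_sources
from .resistance import ResistanceTable, default_resistance_table, integrated_resistance
from .connectivity import (
    CostGraph, barrier_scan, circuit_solve, composite_priority,
    current_centrality, least_cost_corridors, pinch_points,
)

log = logging.getLogger(__name__)

STAGES = (
    "generate", "services", "sensitivity", "sources", "resistance",
    "corridors", "barriers", "pinchpoints", "report",
)


@dataclass
class PipelineConfig:
    """One run's configuration: landscape, parameter tables and thresholds."""

    landscape: dict = field(default_factory=dict)   # LandscapeConfig fields or {"fixture": name}
    seed: int = 0
    min_area_km2: float = 10.0
    top_importance_classes: int = 1
    corridor_width_m: float = 1000.0
    pairing: str = "adjacent"
    barrier_r_min_m: float = 200.0
    barrier_r_max_m: float = 1000.0
    top_n: int = 40
    half_saturation: float = 0.5
    resistance_table: str | dict = "default"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.resistance_table is None:
            raise ValueError("config is missing the resistance table")
        if self.pairing not in ("adjacent", "all"):
            raise ValueError("pairing must be 'adjacent' or 'all'")
        if self.min_area_km2 <= 0:
            raise ValueError("min_area_km2 must be > 0")
        self.landscape_config()  # raises on invalid landscape parameters

    def landscape_config(self) -> LandscapeConfig | None:
        """The synthetic-landscape config, or None when a fixture is named."""
        if "fixture" in self.landscape:
            return None
        kwargs = dict(self.landscape)
        kwargs.setdefault("seed", self.seed)
        if "class_proportions" in kwargs:
            kwargs["class_proportions"] = {
                int(k): float(v) for k, v in kwargs["class_proportions"].items()
            }
        if "shape" in kwargs:
            kwargs["shape"] = tuple(kwargs["shape"])
        cfg = LandscapeConfig(**kwargs)
        cfg.validate()
        return cfg

    def table(self) -> ResistanceTable:
        if self.resistance_table == "default":
            return default_resistance_table()
        raise ValueError("custom resistance tables are configured in code")

    def canonical_hash(self) -> str:
        doc = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def demo_config(seed: int = 0) -> PipelineConfig:
    """The bundled desk-scale demonstration configuration (120×120 cells)."""
    return PipelineConfig(
        landscape={"shape": (120, 120), "cell_size": 100.0, "correlation_length": 8.0,
                   "n_reserves": 3, "n_pollution_points": 5},
        seed=seed,
        min_area_km2=1.0,
        barrier_r_min_m=200.0,
        barrier_r_max_m=1000.0,
        top_n=40,
    )


@dataclass
class PipelineResult:
    """All in-memory artifacts of one run (rasters keyed by layer name)."""

    bundle: LandscapeBundle
    rasters: dict[str, RasterGrid]
    sources: list[SourcePatch]
    corridors: list
    barriers: list
    pinch_points: list
    node_centrality: dict
    composite: dict
    composition: dict[str, float]
    manifest: dict


def _distance_or_far(ref: RasterGrid, mask: np.ndarray, far_m: float = 1e7) -> RasterGrid:
    """Distance to targets, or a uniform very-far distance if none exist."""
    if mask.any():
        return euclidean_distance(ref, mask)
    far = np.full(ref.shape, far_m)
    far[ref.nodata_mask] = np.nan
    return ref.with_values(far)


def csle_factors_from_bundle(bundle: LandscapeBundle) -> CSLEFactors:
    """Synthetic CSLE factor surfaces derived from the landscape layers.

    Proxy formulations (documented in the methods note): erosivity scales
    with annual precipitation, erodibility varies weakly and inversely with
    vegetation, LS comes from the terrain helper, and the management factors
    C/P/T are land-cover lookups.
    """
    lulc = bundle.lulc
    lv = lulc.values.astype(int)

    def by_category(table: dict[str, float]) -> RasterGrid:
        out = np.zeros(lulc.shape, dtype=float)
        for code in np.unique(lv[lulc.valid_mask]):
            out[lv == code] = table[landcover.category_of(int(code))]
        out[lulc.nodata_mask] = np.nan
        return lulc.with_values(out)

    R = bundle.precipitation.with_values(0.5 * bundle.precipitation.values)
    K = bundle.ndvi.with_values(0.025 + 0.01 * (1.0 - bundle.ndvi.values))
    LS = ls_factor(bundle.dem)
    C = by_category({"forest": 0.01, "wetland": 0.02, "grassland": 0.06,
                     "cropland": 0.25, "water": 0.0, "barren": 0.6, "built": 0.1})
    P = by_category({"forest": 1.0, "wetland": 1.0, "grassland": 1.0,
                     "cropland": 0.5, "water": 1.0, "barren": 1.0, "built": 0.2})
    T = by_category({"forest": 1.0, "wetland": 1.0, "grassland": 1.0,
                     "cropland": 0.8, "water": 1.0, "barren": 1.0, "built": 1.0})
    return CSLEFactors(R=R, K=K, LS=LS, C=C, P=P, T=T)


def resistance_from_bundle(
    bundle: LandscapeBundle, table: ResistanceTable | None = None
) -> RasterGrid:
    """Integrated resistance surface of a landscape bundle (six-factor overlay)."""
    table = table or default_resistance_table()
    lulc = bundle.lulc
    factor_rasters = {
        "lulc": lulc,
        "relief": relief(bundle.dem),
        "slope": slope(bundle.dem),
        "road1_dist": _distance_or_far(lulc, rasterize_lines(lulc, bundle.roads_1)),
        "road2_dist": _distance_or_far(lulc, rasterize_lines(lulc, bundle.roads_2)),
        "pollution_dist": _distance_or_far(lulc, rasterize_points(lulc, bundle.pollution_points)),
    }
    return integrated_resistance(factor_rasters, table)


def _stats(r: RasterGrid) -> dict:
    v = r.valid_values.astype(float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {"n": 0}
    return {"n": int(v.size), "min": float(v.min()),
            "mean": float(v.mean()), "max": float(v.max())}


def run(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute every stage in order; write artifacts when ``out_dir`` is given."""
    config.validate()
    manifest: dict = {
        "config_hash": config.canonical_hash(),
        "seed": config.seed,
        "versions": {"ecolink": __version__, "numpy": np.__version__},
        "stages": {},
    }
    rasters: dict[str, RasterGrid] = {}

    # -- generate ------------------------------------------------------------
    if "fixture" in config.landscape:
        bundle = make_fixture(config.landscape["fixture"],
                              shape=tuple(config.landscape.get("shape", (60, 60))),
                              cell_size=config.landscape.get("cell_size", 30.0))
    else:
        bundle = generate(config.landscape_config())
    bundle.validate()
    rasters.update(bundle.rasters())
    manifest["stages"]["generate"] = {k: _stats(v) for k, v in bundle.rasters().items()}

    lulc = bundle.lulc

    # -- services ------------------------------------------------------------
    threats = default_threats(lulc, bundle.roads_1, bundle.roads_2)
    params = default_habitat_params()
    params.half_saturation = config.half_saturation
    D = degradation(lulc, threats, params)
    Q = habitat_quality(D, lulc, params)
    Y = water_yield(bundle.precipitation, bundle.aet)
    C = carbon_storage(lulc, default_carbon_pools())
    services_int = integrated_services(Q, Y, C)
    rasters.update({"degradation": D, "habitat_quality": Q, "water_yield": Y,
                    "carbon": C, "services_integrated": services_int})
    manifest["stages"]["services"] = {
        k: _stats(rasters[k])
        for k in ("habitat_quality", "water_yield", "carbon", "services_integrated")
    }

    # -- sensitivity ---------------------------------------------------------
    road_mask = rasterize_lines(lulc, bundle.roads_1)
    road_dist = _distance_or_far(lulc, road_mask)
    reserve_mask = rasterize_polygons(lulc, bundle.reserves)
    reserve_dist = _distance_or_far(lulc, reserve_mask)
    habitat_s = habitat_sensitivity(road_dist, reserve_dist, lulc, bundle.ndvi)

    water_mask = np.isin(lulc.values.astype(int), sorted(landcover.WATER)) & lulc.valid_mask
    water_dist = _distance_or_far(lulc, water_mask)
    pts = bundle.pollution_points
    waste_pts, air_pts = pts[0::2], pts[1::2]  # alternate plants into the two classes
    waste_dist = _distance_or_far(lulc, rasterize_points(lulc, waste_pts))
    air_dist = _distance_or_far(lulc, rasterize_points(lulc, air_pts))
    water_s = water_sensitivity(water_dist, waste_dist, air_dist)

    soil_A = csle(csle_factors_from_bundle(bundle))
    sensitivity_int, sensitivity_classes = integrated_sensitivity(habitat_s, water_s, soil_A)
    rasters.update({"habitat_sensitivity": habitat_s, "water_sensitivity": water_s,
                    "soil_loss": soil_A, "sensitivity_integrated": sensitivity_int,
                    "sensitivity_classes": sensitivity_classes})
    manifest["stages"]["sensitivity"] = {
        k: _stats(rasters[k])
        for k in ("habitat_sensitivity", "water_sensitivity", "soil_loss",
                  "sensitivity_integrated")
    }

    # -- sources -------------------------------------------------------------
    importance, importance_classes = ecological_importance(services_int, sensitivity_int)
    src = select_sources(importance_classes, bundle.reserves,
                         min_area_km2=config.min_area_km2,
                         top_classes=config.top_importance_classes)
    label_grid = np.zeros(lulc.shape, dtype=float)
    for p in src:
        label_grid[p.mask] = p.id
    rasters.update({"importance": importance, "importance_classes": importance_classes,
                    "source_labels": lulc.with_values(label_grid)})
    manifest["stages"]["sources"] = {
        "count": len(src),
        "area_km2": float(sum(p.area_km2 for p in src)),
        "redline_patches": int(sum(p.from_redline for p in src)),
    }

    # -- resistance ----------------------------------------------------------
    res = resistance_from_bundle(bundle, config.table())
    rasters["resistance"] = res
    manifest["stages"]["resistance"] = _stats(res)

    # -- corridors (LCP + circuit) -------------------------------------------
    graph = CostGraph(res)
    corridors, cwd = least_cost_corridors(
        graph, src, pairing=config.pairing, corridor_width_m=config.corridor_width_m
    )
    by_id = {p.id: p for p in src}
    current_maps = {}
    for c in corridors:
        sol = circuit_solve(graph, by_id[c.source_a], by_id[c.source_b])
        current_maps[c.pair] = sol.current
    if len(src) >= 2 and corridors:
        node_cent, _link_cent = current_centrality(src, corridors)
    else:
        node_cent = {}
    manifest["stages"]["corridors"] = {
        "count": len(corridors),
        "total_length_km": float(sum(c.length_km for c in corridors)),
    }

    # -- barriers and pinch points -------------------------------------------
    barriers, is_grid = barrier_scan(
        graph, corridors, cwd,
        r_min_m=config.barrier_r_min_m, r_max_m=config.barrier_r_max_m,
        top_n=config.top_n,
    )
    points, pinch_grid = pinch_points(current_maps, corridors, top_n=config.top_n)
    composite = composite_priority(corridors)
    rasters["improvement_score"] = is_grid
    rasters["pinch_score"] = pinch_grid
    manifest["stages"]["barriers"] = {"count": len(barriers)}
    manifest["stages"]["pinchpoints"] = {"count": len(points)}

    # -- report --------------------------------------------------------------
    composition = corridor_composition(lulc, corridors)
    manifest["stages"]["report"] = {
        "priority_corridors": sum(1 for v in composite.values() if v == "V&V"),
        "composition": composition,
    }

    result = PipelineResult(
        bundle=bundle, rasters=rasters, sources=src, corridors=corridors,
        barriers=barriers, pinch_points=points, node_centrality=node_cent,
        composite=composite, composition=composition, manifest=manifest,
    )
    if out_dir is not None:
        write_artifacts(result, Path(out_dir))
    return result


def corridor_composition(lulc: RasterGrid, corridors) -> dict[str, float]:
    """Land-cover percentages inside the union of 1 km corridor buffers."""
    union = np.zeros(lulc.shape, dtype=bool)
    for c in corridors:
        union |= c.buffer_mask
    union &= lulc.valid_mask
    total = union.sum()
    if total == 0:
        return {}
    lv = lulc.values.astype(int)[union]
    out: dict[str, float] = {}
    for code in np.unique(lv):
        name = landcover.LULC_LEGEND[int(code)]
        out[name] = float(100.0 * (lv == code).sum() / total)
    return out


def _geojson_feature(geom, props) -> dict:
    from shapely.geometry import mapping
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}


def write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    """Write rasters (.asc), vectors (GeoJSON), tables (CSV) and the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, r in result.rasters.items():
        write_ascii_grid(r, out_dir / f"{name}.asc")

    from shapely.geometry import Point

    src_features = []
    for p in result.sources:
        geom = Point(p.centroid)
        src_features.append(_geojson_feature(geom, {
            "id": p.id, "area_km2": p.area_km2, "from_redline": p.from_redline,
            "centrality": result.node_centrality.get(p.id),
        }))
    (out_dir / "sources.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": src_features}, indent=1))

    cor_features = [
        _geojson_feature(c.polyline, {
            "source_a": c.source_a, "source_b": c.source_b,
            "lcp_cost": c.lcp_cost, "length_km": c.length_km,
            "centrality": c.centrality,
            "improvement_level": c.improvement_level,
            "priority_level": c.priority_level,
            "composite": result.composite.get(c.pair),
        })
        for c in result.corridors
    ]
    (out_dir / "corridors.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": cor_features}, indent=1))

    pd.DataFrame([{
        "source_a": c.source_a, "source_b": c.source_b, "lcp_cost": c.lcp_cost,
        "length_km": c.length_km, "centrality": c.centrality,
        "improvement_score": c.improvement_score, "priority_score": c.priority_score,
        "improvement_level": c.improvement_level, "priority_level": c.priority_level,
        "composite": result.composite.get(c.pair),
    } for c in result.corridors]).to_csv(out_dir / "corridors.csv", index=False)

    pd.DataFrame([{
        "row": b.cell[0], "col": b.cell[1], "radius_m": b.radius_m,
        "improvement_score": b.score, "source_a": b.pair[0], "source_b": b.pair[1],
    } for b in result.barriers]).to_csv(out_dir / "barriers.csv", index=False)

    pd.DataFrame([{
        "rank": p.rank, "row": p.cell[0], "col": p.cell[1], "current": p.score,
    } for p in result.pinch_points]).to_csv(out_dir / "pinch_points.csv", index=False)

    pd.Series(result.composition, name="percent").rename_axis("lulc").to_csv(
        out_dir / "corridor_composition.csv")

    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=1, sort_keys=True))


def report(run_dir) -> dict:
    """Summarize a finished run directory from its written artifacts."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    corridors = pd.read_csv(run_dir / "corridors.csv")
    srcs = json.loads((run_dir / "sources.geojson").read_text())["features"]
    comp = pd.read_csv(run_dir / "corridor_composition.csv")
    summary = {
        "seed": manifest["seed"],
        "n_sources": len(srcs),
        "source_area_km2": float(sum(f["properties"]["area_km2"] for f in srcs)),
        "n_corridors": int(len(corridors)),
        "total_corridor_length_km": float(corridors["length_km"].sum()) if len(corridors) else 0.0,
        "priority_corridors": int((corridors["composite"] == "V&V").sum()) if len(corridors) else 0,
        "composition_percent": dict(zip(comp.iloc[:, 0], comp["percent"])),
    }
    (run_dir / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
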