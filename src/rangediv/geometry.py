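"""Range geometry and phenotype variables.

Planar polygon metrics (area, perimeter, shape index = area/perimeter,
bounding-box extents and midpoints), island/continental classification
against a continental mask, the hand-wing index, phylogenetic (Brownian)
and genus-mean imputation of missing trait values, and model-frame
preparation (log transforms, absolute positions, z-scoring).

All geometry is planar, on equal-area-projected coordinates in km;
projection is upstream metadata.  Shapely backs every polygon operation.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, shape
from shapely import wkt as _wkt

from .trees import Tree, phylo_vcv

__all__ = [
    "polygon_metrics",
    "extent_metrics",
    "classify_geographic_setting",
    "hand_wing_index",
    "species_hwi",
    "impute_trait_bm",
    "genus_mean_impute",
    "prepare_model_frame",
    "load_ranges_geojson",
    "load_ranges_wkt",
]


def _as_multipolygon(polygons, species: str = "?") -> MultiPolygon:
    if isinstance(polygons, MultiPolygon):
        geom = polygons
    elif isinstance(polygons, Polygon):
        geom = MultiPolygon([polygons])
    else:
        parts = list(polygons)
        if not parts:
            raise ValueError(f"{species}: empty polygon set")
        geom = MultiPolygon(
            [p if isinstance(p, Polygon) else Polygon(p) for p in parts]
        )
    if geom.is_empty:
        raise ValueError(f"{species}: empty polygon set")
    if not geom.is_valid:
        raise ValueError(
            f"{species}: invalid (e.g. self-intersecting) range polygon"
        )
    return geom


def polygon_metrics(polygons, species: str = "?") -> tuple[float, float, float]:
    """(area km^2, perimeter km, shape index km) of a range polygon set.

    Areas of parts sum (holes subtract) and perimeters sum over all
    rings, so disjunct multi-part ranges accumulate perimeter and get a
    smaller shape index — small values mean elongated or disjunct
    ranges.
    """
    geom = _as_multipolygon(polygons, species)
    area = geom.area
    perimeter = geom.length
    if area <= 0:
        raise ValueError(f"{species}: zero-area range polygon")
    return float(area), float(perimeter), float(area / perimeter)


def extent_metrics(
    polygons,
    species: str = "?",
    km_per_deg_lat: float = 111.32,
    km_per_deg_lon: float = 111.32,
    origin_deg: tuple[float, float] = (0.0, 0.0),
):
    """Bounding-box extents and midpoints of a range polygon set.

    Returns a dict with box length (east-west, km), width (north-south,
    km), midpoints in degrees (box centre mapped through the declared
    plate-carree-style scaling), and the area-weighted centroid in
    projected km.  Midpoints, not centroids, feed the regressions.
    """
    geom = _as_multipolygon(polygons, species)
    x0, y0, x1, y1 = geom.bounds
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    centroid = geom.centroid
    return {
        "length_km": float(x1 - x0),
        "width_km": float(y1 - y0),
        "lon_midpoint": origin_deg[1] + cx / km_per_deg_lon,
        "lat_midpoint": origin_deg[0] + cy / km_per_deg_lat,
        "centroid_x_km": float(centroid.x),
        "centroid_y_km": float(centroid.y),
    }


def classify_geographic_setting(polygons, continental_mask, species: str = "?") -> str:
    """"continental" iff any part of the range overlaps the mask
    (Australia/Tasmania/New Guinea in the empirical setting), else
    "island"; any overlap suffices, containment is not required."""
    if continental_mask is None:
        raise ValueError("a continental mask polygon is required")
    geom = _as_multipolygon(polygons, species)
    mask = _as_multipolygon(continental_mask, "continental_mask")
    return "continental" if geom.intersects(mask) else "island"


def hand_wing_index(kipps, wing_length):
    """HWI = 100 * Kipp's distance / wing length (both mm)."""
    kipps = np.asarray(kipps, dtype=float)
    wing_length = np.asarray(wing_length, dtype=float)
    if (wing_length <= 0).any():
        raise ValueError("wing length must be positive")
    if (kipps < 0).any() or (kipps > wing_length).any():
        raise ValueError("Kipp's distance must lie in [0, wing length]")
    out = 100.0 * kipps / wing_length
    return float(out) if out.ndim == 0 else out


def species_hwi(measurements: pd.DataFrame) -> pd.Series:
    """Per-species HWI from individual measurements.

    Expects columns ``species``, ``kipps``, ``wing_length``; individual
    measurements are averaged per species *before* the ratio is taken.
    """
    means = measurements.groupby("species")[["kipps", "wing_length"]].mean()
    return pd.Series(
        hand_wing_index(means["kipps"], means["wing_length"]),
        index=means.index,
        name="hwi",
    )


def impute_trait_bm(tree: Tree, trait: pd.Series) -> pd.Series:
    """Fill missing tip values with their Brownian conditional expectation.

    Given observed tips o and missing tips m, the imputed values are the
    conditional mean mu + C_mo C_oo^-1 (x_o - mu) of the multivariate
    normal implied by the tree covariance C, with the ancestral mean mu
    estimated by GLS.  Observed values are returned unchanged.
    """
    trait = pd.Series(trait, dtype=float)
    C = phylo_vcv(tree)
    trait = trait.reindex(C.labels)
    obs = trait.notna()
    n_obs = int(obs.sum())
    if n_obs == len(trait):
        return trait
    if n_obs < 2:
        raise ValueError("need at least two observed values to impute")
    if n_obs <= len(trait) / 2:
        raise ValueError("more than half the tips are missing")
    V = C.matrix
    oo = V.loc[obs, obs].to_numpy()
    mo = V.loc[~obs, obs].to_numpy()
    xo = trait[obs].to_numpy()
    ones = np.ones(n_obs)
    sol = np.linalg.solve(oo, np.column_stack([xo, ones]))
    mu = float(ones @ sol[:, 0] / (ones @ sol[:, 1]))
    imputed = mu + mo @ np.linalg.solve(oo, xo - mu)
    out = trait.copy()
    out[~obs] = imputed
    return out


def genus_mean_impute(values: pd.Series, genus: pd.Series) -> pd.Series:
    """Fill missing values with the mean of observed congeners
    (falling back to the overall mean for an all-missing genus)."""
    values = pd.Series(values, dtype=float)
    genus = genus.reindex(values.index)
    filled = values.fillna(values.groupby(genus).transform("mean"))
    return filled.fillna(values.mean())


def prepare_model_frame(
    dataset: pd.DataFrame,
    columns: list[str],
    log_columns: tuple[str, ...] = ("range_size", "shape_index", "body_mass", "hwi"),
    abs_columns: tuple[str, ...] = ("lat_midpoint", "lon_midpoint"),
    standardize: bool = True,
):
    """Build a regression-ready frame and a transform manifest.

    Requested positive continuous columns are natural-log transformed,
    positional midpoints are replaced by absolute values, the ``setting``
    column becomes a 0/1 island indicator, and continuous predictors are
    z-scored (mean 0, sd 1) so effect sizes are comparable.  Returns
    (frame, manifest dict).
    """
    missing = [c for c in columns if c not in dataset.columns]
    if missing:
        raise KeyError(f"columns not in dataset: {missing}")
    frame = pd.DataFrame(index=dataset.index)
    manifest: dict[str, dict] = {}
    for col in columns:
        x = dataset[col]
        steps: list[str] = []
        if col == "setting":
            x = (x == "island").astype(float)
            frame["island"] = x
            manifest["island"] = {"source": "setting", "steps": ["island==1"]}
            continue
        if col in log_columns:
            bad = x[x <= 0]
            if len(bad):
                raise ValueError(
                    f"non-positive value routed to log in {col!r} for "
                    f"species {list(bad.index[:3])}"
                )
            x = np.log(x)
            steps.append("ln")
        if col in abs_columns:
            x = x.abs()
            steps.append("abs")
        if standardize:
            sd = x.std(ddof=0)
            if sd == 0:
                raise ValueError(f"column {col!r} is constant")
            x = (x - x.mean()) / sd
            steps.append("zscore")
        frame[col] = x
        manifest[col] = {"source": col, "steps": steps}
    return frame, manifest


# ---------------------------------------------------------------------------
# range-file I/O


def load_ranges_geojson(path) -> dict[str, MultiPolygon]:
    """Read one GeoJSON FeatureCollection; species label from the
    ``name`` property of each feature."""
    with open(path) as fh:
        doc = json.load(fh)
    out: dict[str, MultiPolygon] = {}
    for feat in doc.get("features", []):
        name = feat.get("properties", {}).get("name")
        if not name:
            raise ValueError("feature without a 'name' property")
        out[name] = _as_multipolygon(shape(feat["geometry"]), name)
    return out


def load_ranges_wkt(path) -> dict[str, MultiPolygon]:
    """Read tab-separated ``species<TAB>WKT`` lines."""
    out: dict[str, MultiPolygon] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, txt = line.split("\t", 1)
            out[name] = _as_multipolygon(_wkt.loads(txt), name)
    return out
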