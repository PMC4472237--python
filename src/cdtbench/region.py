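"""Study-region model: spatial units with coordinates and at-risk populations.

A study region is a set of spatial units (SUs) — ZIP-code-like administrative
tracts — each carrying a planar centroid and an at-risk population size
(here, mean annual live births). Coordinates are assumed to be in a projected
planar system so that Euclidean distance between centroids is meaningful;
no geodesic math is performed anywhere in the package.

Regions can be loaded from CSV (columns ``id,x,y,population``), optionally
joined with a GeoJSON FeatureCollection carrying polygons for mapping, or
generated synthetically to emulate a realistic geography: an irregular
(jittered-grid) layout of ~200 SUs with a strongly right-skewed population
distribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpatialUnit",
    "StudyRegion",
    "load_region",
    "write_region",
    "load_polygons",
    "write_polygons",
    "generate_synthetic_region",
]

# Fig-1-style population quartile cut points (births/year) used as defaults
# for synthetic regions.
DEFAULT_POPULATION_QUARTILES = (17.0, 35.0, 70.0)

# Standard-normal quartile: lognormal quartiles are exp(mu -/+ z75*sigma).
_Z75 = 0.6744897501960817


@dataclass(frozen=True)
class SpatialUnit:
    """One spatial unit: identifier, planar centroid, at-risk population."""

    id: object
    x: float
    y: float
    population: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"SU {self.id!r}: non-finite coordinates")
        if not math.isfinite(self.population) or self.population < 0:
            raise ValueError(f"SU {self.id!r}: population must be finite and >= 0")


class StudyRegion:
    """An ordered collection of spatial units with cached array views.

    Parameters
    ----------
    units
        Spatial units in a fixed (file) order.
    polygons
        Optional mapping from SU id to a GeoJSON geometry dict (``Polygon``
        or ``MultiPolygon``), used only for rendering maps.
    """

    def __init__(self, units: list[SpatialUnit], polygons: dict | None = None):
        if len(units) < 2:
            raise ValueError("a study region needs at least 2 spatial units")
        ids = [u.id for u in units]
        if len(set(ids)) != len(ids):
            seen: set = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate SU id: {i!r}")
                seen.add(i)
        self.units: list[SpatialUnit] = list(units)
        self.ids: list = ids
        self.x = np.array([u.x for u in units], dtype=float)
        self.y = np.array([u.y for u in units], dtype=float)
        self.population = np.array([u.population for u in units], dtype=float)
        if not (self.population > 0).any():
            raise ValueError("at least one SU must have population > 0")
        self.total_population: float = float(self.population.sum())
        self.index_of: dict = {i: k for k, i in enumerate(ids)}
        self.polygons = polygons

    @property
    def n(self) -> int:
        return len(self.units)

    def distances_from(self, k: int) -> np.ndarray:
        """Euclidean centroid distances from SU at positional index ``k``."""
        return np.hypot(self.x - self.x[k], self.y - self.y[k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "x": self.x, "y": self.y, "population": self.population}
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"StudyRegion(n={self.n}, N={self.total_population:g})"


def load_region(source, geometry=None) -> StudyRegion:
    """Load a study region from a CSV path or DataFrame.

    ``source`` must provide columns ``id, x, y, population`` with unique ids,
    numeric coordinates and nonnegative populations. ``geometry`` may be a
    GeoJSON FeatureCollection path/dict whose features carry an ``id``
    property matching the table.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, float_precision="round_trip")
    missing = {"id", "x", "y", "population"} - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    units = [
        SpatialUnit(row.id, float(row.x), float(row.y), float(row.population))
        for row in df.itertuples(index=False)
    ]
    polygons = load_polygons(geometry) if geometry is not None else None
    region = StudyRegion(units, polygons=polygons)
    return region


def write_region(region: StudyRegion, path) -> None:
    """Write the region table as CSV (columns ``id,x,y,population``).

    Floats use shortest-round-trip formatting so a written region re-reads
    bit-identically.
    """
    region.to_frame().to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def load_polygons(geometry) -> dict:
    """Read SU polygons from a GeoJSON FeatureCollection (path or dict)."""
    if isinstance(geometry, (str, bytes)) or hasattr(geometry, "__fspath__"):
        with open(geometry) as fh:
            gj = json.load(fh)
    else:
        gj = geometry
    if gj.get("type") != "FeatureCollection":
        raise ValueError("geometry must be a GeoJSON FeatureCollection")
    polygons = {}
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if "id" not in props:
            raise ValueError("every feature needs an 'id' property")
        polygons[props["id"]] = feat["geometry"]
    return polygons


def write_polygons(region: StudyRegion, path, extra_properties=None) -> None:
    """Write region polygons (and optional per-SU properties) as GeoJSON."""
    if region.polygons is None:
        raise ValueError("region has no polygons")
    features = []
    for uid in region.ids:
        props = {"id": uid}
        if extra_properties is not None:
            props.update(extra_properties.get(uid, {}))
        features.append(
            {"type": "Feature", "properties": props, "geometry": region.polygons[uid]}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _lognormal_params(quartiles) -> tuple[float, float]:
    """Fit (mu, sigma) of a log-normal to three quartile cut points."""
    q1, q2, q3 = (float(q) for q in quartiles)
    if not (0 < q1 < q2 < q3):
        raise ValueError("quartile cut points must be positive and strictly increasing")
    mu = math.log(q2)
    sigma = 0.5 * (math.log(q3 / q2) + math.log(q2 / q1)) / _Z75
    return mu, sigma


def generate_synthetic_region(
    n_units: int = 221,
    population_quartiles=DEFAULT_POPULATION_QUARTILES,
    layout: str = "jittered-grid",
    seed: int | None = None,
    with_polygons: bool = False,
) -> StudyRegion:
    """Generate a reproducible synthetic study region.

    The layout is a square lattice at unit spacing, truncated to ``n_units``
    nodes; the default ``jittered-grid`` perturbs each centroid uniformly by
    up to ±0.25 in x and y so that pairwise distances are essentially free of
    ties while the geography stays irregular. Populations are drawn from a
    log-normal whose parameters are fit to the requested quartile cut points
    (default 17/35/70 births per year — a strongly right-skewed distribution
    typical of mixed rural/urban birth registries).

    With ``with_polygons=True`` each SU is given its unit lattice cell as a
    square polygon, which is enough to exercise the mapping layer.
    """
    if n_units < 4:
        raise ValueError("n_units must be >= 4 (clusters of 4 SUs impossible otherwise)")
    if layout not in ("grid", "jittered-grid"):
        raise ValueError(f"unknown layout: {layout!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    side = math.ceil(math.sqrt(n_units))
    gx, gy = np.meshgrid(np.arange(side, dtype=float), np.arange(side, dtype=float))
    gx, gy = gx.ravel()[:n_units], gy.ravel()[:n_units]
    if layout == "jittered-grid":
        jitter = rng.uniform(-0.25, 0.25, size=(2, n_units))
        x, y = gx + jitter[0], gy + jitter[1]
    else:
        x, y = gx, gy
    mu, sigma = _lognormal_params(population_quartiles)
    population = rng.lognormal(mean=mu, sigma=sigma, size=n_units)
    units = [
        SpatialUnit(int(i), float(x[i]), float(y[i]), float(population[i]))
        for i in range(n_units)
    ]
    polygons = None
    if with_polygons:
        polygons = {}
        for i in range(n_units):
            cx, cy = gx[i], gy[i]
            ring = [
                [cx - 0.5, cy - 0.5],
                [cx + 0.5, cy - 0.5],
                [cx + 0.5, cy + 0.5],
                [cx - 0.5, cy + 0.5],
                [cx - 0.5, cy - 0.5],
            ]
            polygons[int(i)] = {"type": "Polygon", "coordinates": [ring]}
    return StudyRegion(units, polygons=polygons)
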