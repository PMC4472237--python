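"""Performance maps: one indicator value per SU, rendered as choropleths.

Every simulated cluster is centered on one SU, so its indicator (TC_a,
TC_c or usual power) can be assigned to that central SU, giving exactly
one value per SU of the region — one map layer per indicator and risk
combination (incidence, relative risk).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .region import StudyRegion
from .metrics import PerformanceSummary

__all__ = ["PerformanceMapLayer", "build_map_layer", "render_map"]

_INDICATORS = ("tc_a", "tc_c", "power")


@dataclass
class PerformanceMapLayer:
    """Per-SU values of one indicator for one risk combination."""

    indicator: str
    values: dict            # SU id -> value in [0, 1]
    incidence: float | None = None
    relative_risk: float | None = None

    def label(self) -> str:
        parts = [self.indicator]
        if self.incidence is not None:
            parts.append(f"I{self.incidence:g}")
        if self.relative_risk is not None:
            parts.append(f"RR{self.relative_risk:g}")
        return "_".join(parts)


def build_map_layer(
    region: StudyRegion,
    summaries: list[PerformanceSummary],
    indicator: str,
    incidence: float | None = None,
    relative_risk: float | None = None,
) -> PerformanceMapLayer:
    """Assign each cluster's indicator to its central SU.

    Requires exactly one summary per SU-centered cluster; duplicate or
    missing centers are hard errors.
    """
    if indicator not in _INDICATORS:
        raise ValueError(f"indicator must be one of {_INDICATORS}")
    values: dict = {}
    for s in summaries:
        cid = s.cluster.center_id
        if cid in values:
            raise ValueError(f"duplicate summary for center SU {cid!r}")
        if cid not in region.index_of:
            raise ValueError(f"summary center {cid!r} not in region")
        if indicator == "tc_a":
            values[cid] = s.tc_a
        elif indicator == "tc_c":
            values[cid] = s.tc_c
        else:
            values[cid] = s.usual_power
    missing = [i for i in region.ids if i not in values]
    if missing:
        raise ValueError(f"missing summaries for center SUs: {missing[:10]}")
    return PerformanceMapLayer(
        indicator=indicator,
        values=values,
        incidence=incidence,
        relative_risk=relative_risk,
    )


def _polygon_patches(geometry):
    """Yield exterior rings of a GeoJSON Polygon/MultiPolygon as arrays."""
    if geometry["type"] == "Polygon":
        rings = [geometry["coordinates"][0]]
    elif geometry["type"] == "MultiPolygon":
        rings = [poly[0] for poly in geometry["coordinates"]]
    else:
        raise ValueError(f"unsupported geometry type: {geometry['type']}")
    for ring in rings:
        yield np.asarray(ring, dtype=float)


def render_map(
    layer: PerformanceMapLayer,
    region: StudyRegion,
    image_path,
    geojson_path=None,
    n_classes: int = 5,
):
    """Write a choropleth image and an attributed GeoJSON for one layer.

    Values are shaded on a fixed [0, 1] scale cut into ``n_classes`` equal
    classes (monotone colormap), so maps of different risk combinations are
    directly comparable. The GeoJSON features carry
    ``{su_id, indicator, value, incidence, rr}`` with the layer's values
    serialized untouched.
    """
    if region.polygons is None:
        raise ValueError("region has no polygons; cannot render a map")
    missing = [i for i in region.ids if i not in region.polygons]
    if missing:
        raise ValueError(f"missing polygons for SUs: {missing[:10]}")

    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import pyplot as plt
    from matplotlib.collections import PolyCollection
    from matplotlib.colors import BoundaryNorm

    verts, vals = [], []
    for uid in region.ids:
        for ring in _polygon_patches(region.polygons[uid]):
            verts.append(ring)
            vals.append(layer.values[uid])
    bounds = np.linspace(0.0, 1.0, n_classes + 1)
    cmap = plt.get_cmap("viridis", n_classes)
    norm = BoundaryNorm(bounds, n_classes)
    fig, ax = plt.subplots(figsize=(6, 6))
    coll = PolyCollection(verts, array=np.array(vals), cmap=cmap, norm=norm,
                          edgecolors="white", linewidths=0.3)
    ax.add_collection(coll)
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_title(layer.label())
    fig.colorbar(coll, ax=ax, ticks=bounds, shrink=0.8)
    fig.savefig(image_path, dpi=150)
    plt.close(fig)

    if geojson_path is not None:
        features = []
        for uid in region.ids:
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "su_id": uid,
                        "indicator": layer.indicator,
                        "value": layer.values[uid],
                        "incidence": layer.incidence,
                        "rr": layer.relative_risk,
                    },
                    "geometry": region.polygons[uid],
                }
            )
        with open(geojson_path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
    return image_path, geojson_path
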