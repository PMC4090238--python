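"""Decision products built from a risk matrix.

Forward profiles rank the likeliest destinations for a pest at a given
origin cell; reverse profiles rank the likeliest origins for a pest
found at a given destination cell.  For a whole jurisdiction (state or
province) the out-of-jurisdiction origin-risk map sums φ_ij over all
member destination cells j for every external origin cell i — the
product used to prioritise surveillance and firewood inspection outside
the target region.  Cells are labelled moderate-to-high risk above a
fixed φ threshold (default 1e-4, strict inequality).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import Point, shape

from .grid import GridSpec
from .network import RiskMatrix

HOTSPOT_THRESHOLD = 0.0001


@dataclass(frozen=True)
class Jurisdiction:
    """A named set of member grid cells (a state or province)."""

    name: str
    cells: frozenset[int]

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError(f"jurisdiction {self.name!r} has an empty member set")

    @classmethod
    def from_cells(cls, name: str, cells) -> "Jurisdiction":
        return cls(name=name, cells=frozenset(int(c) for c in cells))

    @classmethod
    def from_polygon(
        cls, name: str, geometry, grid: GridSpec, candidate_cells
    ) -> "Jurisdiction":
        """Membership by point-in-polygon test of cell centers.

        ``geometry`` is a shapely geometry or GeoJSON-like mapping in
        lon/lat; each candidate cell belongs iff its center falls inside.
        Border cells therefore belong to exactly one jurisdiction when
        polygons do not overlap.
        """
        geom = geometry if hasattr(geometry, "contains") else shape(geometry)
        members = []
        for c in candidate_cells:
            lon, lat = grid.cell_center(c)
            if geom.contains(Point(float(lon[0]), float(lat[0]))):
                members.append(int(c))
        return cls(name=name, cells=frozenset(members))


@dataclass
class OriginRiskMap:
    """Per-external-cell summed risk into a target jurisdiction."""

    target: str
    values: dict[int, float] = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)


def _sorted_profile(items: dict[int, float]) -> dict[int, float]:
    # descending risk, ties broken by ascending cell id
    return dict(sorted(items.items(), key=lambda kv: (-kv[1], kv[0])))


def forward_profile(phi: RiskMatrix, origin: int) -> dict[int, float]:
    """Row i of φ: destinations reachable from ``origin``, risk-ranked."""
    if origin not in phi.nodes:
        raise KeyError(f"origin cell {origin} not in risk matrix")
    m = phi.sims_per_origin
    row = {j: c / m for (i, j), c in phi.counts.items() if i == origin and c > 0}
    return _sorted_profile(row)


def reverse_profile(phi: RiskMatrix, destination: int) -> dict[int, float]:
    """Column j of φ: origins with positive risk into ``destination``, ranked."""
    if destination not in phi.nodes:
        raise KeyError(f"destination cell {destination} not in risk matrix")
    m = phi.sims_per_origin
    col = {i: c / m for (i, j), c in phi.counts.items() if j == destination and c > 0}
    return _sorted_profile(col)


def jurisdiction_origin_risk(phi: RiskMatrix, target: Jurisdiction) -> OriginRiskMap:
    """Sum φ_ij over member destination cells j for every external origin i.

    value(i) = Σ_{j ∈ target} φ_ij for i outside the target with a
    positive sum; identical to summing the member cells' reverse
    profiles restricted to external origins.
    """
    if not target.cells:
        raise ValueError("empty jurisdiction")
    if not (target.cells & set(phi.nodes)):
        raise ValueError(
            f"jurisdiction {target.name!r} shares no cells with the risk matrix"
        )
    m = phi.sims_per_origin
    # accumulate integer tallies first so the sum is exact
    tallies: dict[int, int] = {}
    for (i, j), c in phi.counts.items():
        if j in target.cells and i not in target.cells and c > 0:
            tallies[i] = tallies.get(i, 0) + c
    sums = {i: c / m for i, c in tallies.items()}
    return OriginRiskMap(target=target.name, values=_sorted_profile(sums))


def classify_risk(
    risk_map: OriginRiskMap, hotspot_threshold: float = HOTSPOT_THRESHOLD
) -> OriginRiskMap:
    """Label each cell 'moderate-high' (value > threshold) or 'low'.

    The comparison is strict; zero-valued cells are absent and get no
    label.  Returns the same map with labels filled in.
    """
    if hotspot_threshold <= 0:
        raise ValueError("hotspot_threshold must be positive")
    labels = {}
    for cell, v in risk_map.values.items():
        if v > hotspot_threshold:
            labels[cell] = "moderate-high"
        elif v > 0:
            labels[cell] = "low"
    risk_map.labels = labels
    return risk_map


def export_risk_map(
    risk_map: OriginRiskMap, grid: GridSpec, path, fmt: str = "csv"
) -> None:
    """Write an origin-risk map as CSV or GeoJSON.

    CSV columns: cell, lon, lat, risk, risk_class (cell centers; risk at
    full float precision so a read-back reproduces the map exactly).
    GeoJSON: one polygon feature per cell with the same properties.
    """
    if fmt not in ("csv", "geojson"):
        raise ValueError(f"unknown format {fmt!r}")
    cells = list(risk_map.values)
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cell", "lon", "lat", "risk", "risk_class"])
            for c in cells:
                lon, lat = grid.cell_center(c)
                w.writerow(
                    [
                        c,
                        repr(float(lon[0])),
                        repr(float(lat[0])),
                        repr(risk_map.values[c]),
                        risk_map.labels.get(c, ""),
                    ]
                )
        return
    features = []
    for c in cells:
        ring = [[x, y] for x, y in grid.cell_polygon(c)]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "cell": c,
                    "risk": risk_map.values[c],
                    "risk_class": risk_map.labels.get(c, ""),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_risk_map(path, target: str = "") -> OriginRiskMap:
    """Read back a CSV written by :func:`export_risk_map` (lossless)."""
    df = pd.read_csv(path, keep_default_na=False)
    values = {int(r.cell): float(r.risk) for r in df.itertuples(index=False)}
    labels = {
        int(r.cell): str(r.risk_class)
        for r in df.itertuples(index=False)
        if str(r.risk_class)
    }
    return OriginRiskMap(target=target, values=values, labels=labels)


def plot_risk_map(risk_map: OriginRiskMap, grid: GridSpec, ax=None, **scatter_kw):
    """Basic scatter of cell centers coloured by risk (matplotlib helper)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cells = list(risk_map.values)
    if cells:
        lon, lat = grid.cell_center(cells)
        vals = [risk_map.values[c] for c in cells]
        sc = ax.scatter(lon, lat, c=vals, **scatter_kw)
        plt.colorbar(sc, ax=ax, label="summed phi")
    ax.set_xlabel("lon")
    ax.set_ylabel("lat")
    ax.set_title(f"Out-of-jurisdiction origin risk: {risk_map.target}")
    return ax
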