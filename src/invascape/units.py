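"""Areal unit systems: polygon partitions of the study rectangle.

A :class:`UnitSystem` is one candidate aggregation scale — e.g. one level of
a watershed-like hierarchy, or a county-like partition.  Units are planar
polygons in meters; geometry is handled by shapely and serialized as
GeoJSON FeatureCollections with ``unit_id``/``parent_id`` properties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape
from shapely.strtree import STRtree

from invascape.errors import SystemValidationError

_AREA_TOL = 1e-9  # relative overlap area treated as shared-boundary noise


@dataclass
class UnitSystem:
    """One polygon partition of the study area.

    Parameters
    ----------
    system_id:
        Label of the partition (e.g. ``"H3"`` for the third watershed-like
        level, ``"COUNTY"`` for the non-nested county-like grid).
    table:
        DataFrame indexed by ``unit_id`` with columns ``parent_id``
        (label or ``None``) and ``geometry`` (shapely ``Polygon``).
    """

    system_id: str
    table: pd.DataFrame
    _centroids: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = {"parent_id", "geometry"} - set(self.table.columns)
        if missing:
            raise SystemValidationError(
                f"unit table for {self.system_id!r} lacks columns {sorted(missing)}"
            )
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)
        self.table.index.name = "unit_id"

    def __len__(self) -> int:
        return len(self.table)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def geometries(self) -> list[Polygon]:
        return list(self.table["geometry"])

    def centroids(self) -> pd.DataFrame:
        """Per-unit centroid coordinates (meters), indexed by unit_id."""
        if self._centroids is None:
            cents = [g.centroid for g in self.table["geometry"]]
            self._centroids = pd.DataFrame(
                {"x": [c.x for c in cents], "y": [c.y for c in cents]},
                index=self.table.index,
            )
        return self._centroids

    def bounds(self) -> tuple[float, float, float, float]:
        boxes = np.array([g.bounds for g in self.table["geometry"]])
        return (
            float(boxes[:, 0].min()),
            float(boxes[:, 1].min()),
            float(boxes[:, 2].max()),
            float(boxes[:, 3].max()),
        )

    def validate_no_overlap(self) -> None:
        """Raise if any two units overlap with positive area.

        Shared boundaries are allowed; overlap area above a relative
        tolerance of the smaller polygon is an invariant violation.
        """
        geoms = self.geometries
        tree = STRtree(geoms)
        pairs = tree.query(geoms, predicate="intersects")
        for i, j in zip(*pairs):
            if i >= j:
                continue
            inter = geoms[i].intersection(geoms[j])
            if inter.area > _AREA_TOL * min(geoms[i].area, geoms[j].area):
                a, b = self.table.index[i], self.table.index[j]
                raise SystemValidationError(
                    f"units {a!r} and {b!r} of system {self.system_id!r} "
                    f"overlap with area {inter.area:g}"
                )

    # ------------------------------------------------------------------ IO

    def to_geojson(self, path) -> None:
        """Write a GeoJSON FeatureCollection (deterministic byte output)."""
        features = []
        for unit_id, row in self.table.iterrows():
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(row["geometry"]),
                    "properties": {
                        "unit_id": unit_id,
                        "parent_id": row["parent_id"],
                        "system_id": self.system_id,
                    },
                }
            )
        doc = {"type": "FeatureCollection", "features": features}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
            fh.write("\n")

    @classmethod
    def from_geojson(cls, path, system_id: str | None = None) -> "UnitSystem":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        rows = {}
        sys_id = system_id
        for feat in doc["features"]:
            props = feat.get("properties", {})
            uid = str(props["unit_id"])
            rows[uid] = {
                "parent_id": props.get("parent_id"),
                "geometry": shape(feat["geometry"]),
            }
            sys_id = sys_id or props.get("system_id")
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.index.name = "unit_id"
        return cls(system_id=sys_id or "UNKNOWN", table=table)


def grid_partition(
    extent: tuple[float, float, float, float],
    rows: int,
    cols: int,
    system_id: str,
    parent_of=None,
    offset: tuple[float, float] = (0.0, 0.0),
) -> UnitSystem:
    """Tile a rectangle with a ``rows × cols`` grid of cells.

    ``offset`` shifts interior grid lines by a fraction of a cell in x/y;
    edge cells absorb the shift so the grid still tiles the extent exactly.
    ``parent_of``, if given, maps a cell's (row, col) to its parent unit id.
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise SystemValidationError("extent must have positive area")
    dx = (xmax - xmin) / cols
    dy = (ymax - ymin) / rows
    xs = xmin + dx * (np.arange(cols + 1) + offset[0])
    ys = ymin + dy * (np.arange(rows + 1) + offset[1])
    xs[0], xs[-1] = xmin, xmax
    ys[0], ys[-1] = ymin, ymax
    recs = {}
    for r in range(rows):
        for c in range(cols):
            poly = Polygon(
                [
                    (xs[c], ys[r]),
                    (xs[c + 1], ys[r]),
                    (xs[c + 1], ys[r + 1]),
                    (xs[c], ys[r + 1]),
                ]
            )
            uid = f"{system_id}_{r:03d}_{c:03d}"
            parent = parent_of(r, c) if parent_of else None
            recs[uid] = {"parent_id": parent, "geometry": poly}
    table = pd.DataFrame.from_dict(recs, orient="index")
    table.index.name = "unit_id"
    return UnitSystem(system_id=system_id, table=table)
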