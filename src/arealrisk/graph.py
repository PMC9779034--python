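"""Areal contiguity graphs and the intrinsic CAR structure matrix.

Small-area models for areal counts need a neighbourhood structure: two
areas are neighbours when their boundaries share at least one geographic
point (queen contiguity; a rook variant requiring a shared boundary
segment is available).  This module builds that structure from GeoJSON
polygons or from an explicit edge list, and derives the intrinsic
conditional autoregressive (ICAR) structure matrix

    Q0 = D - W,

with D the diagonal matrix of neighbour counts and W the 0/1 adjacency
indicator.  Q0 is symmetric, has zero row sums, and rank m - c where c is
the number of connected components; the quadratic form u' Q0 u equals the
sum of squared differences over edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import shapely
from shapely.geometry import shape as _shapely_shape

__all__ = [
    "AreaGraph",
    "build_adjacency_from_geojson",
    "build_adjacency_from_edgelist",
    "icar_structure",
    "read_edgelist_csv",
    "write_edgelist_csv",
    "component_report",
]


@dataclass(eq=False)
class AreaGraph:
    """Contiguity structure of a study region.

    Attributes
    ----------
    area_ids:
        Ordered area labels; index order is the canonical area order used
        by every downstream vector.
    edges:
        Unordered neighbour pairs stored as ``(i, j)`` index tuples with
        ``i < j``; symmetric by construction, no self-loops.
    degrees:
        Number of neighbours per area.
    component_labels:
        Connected-component label per area (0-based, ordered by smallest
        member index).
    """

    area_ids: list[str]
    edges: set[tuple[int, int]]
    degrees: np.ndarray = field(init=False)
    component_labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        m = len(self.area_ids)
        if m < 1:
            raise ValueError("an AreaGraph needs at least one area")
        if len(set(self.area_ids)) != m:
            dupes = sorted({a for a in self.area_ids if self.area_ids.count(a) > 1})
            raise ValueError(f"duplicate area id(s): {dupes}")
        norm = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on area index {i} ({self.area_ids[i]})")
            if not (0 <= i < m and 0 <= j < m):
                raise ValueError(f"edge ({i},{j}) out of range for m={m}")
            norm.add((min(i, j), max(i, j)))
        self.edges = norm
        deg = np.zeros(m, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        self.degrees = deg
        g = nx.Graph()
        g.add_nodes_from(range(m))
        g.add_edges_from(self.edges)
        labels = np.empty(m, dtype=int)
        comps = sorted(nx.connected_components(g), key=min)
        for lab, members in enumerate(comps):
            for i in members:
                labels[i] = lab
        self.component_labels = labels

    # -- basic accessors -------------------------------------------------
    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1

    def components(self) -> list[np.ndarray]:
        """Index arrays of each connected component, in label order."""
        return [
            np.flatnonzero(self.component_labels == c)
            for c in range(self.n_components)
        ]

    def neighbors(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_areas)]
        for i, j in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [sorted(n) for n in nbrs]

    def adjacency_matrix(self) -> np.ndarray:
        w = np.zeros((self.n_areas, self.n_areas))
        for i, j in self.edges:
            w[i, j] = w[j, i] = 1.0
        return w

    def index_of(self, area_id: str) -> int:
        try:
            return self.area_ids.index(area_id)
        except ValueError:
            raise KeyError(f"unknown area id '{area_id}'") from None


def _geometry_dimension(geom) -> int:
    if geom.is_empty:
        return -1
    return int(shapely.get_dimensions(geom))


def build_adjacency_from_geojson(
    polygons,
    id_property: str = "id",
    rule: str = "queen",
    epsilon: float = 0.0,
) -> AreaGraph:
    """Build a contiguity graph from a GeoJSON FeatureCollection.

    Parameters
    ----------
    polygons:
        A FeatureCollection dict, a JSON string, or a path to a ``.geojson``
        file.  Every feature must carry a unique id (``properties[id_property]``
        or a top-level ``id``) and a non-empty Polygon/MultiPolygon geometry.
    rule:
        ``"queen"``: areas touching in at least one point (shared segment
        or single shared vertex) are neighbours.  ``"rook"``: the shared
        boundary must have positive length (a lone corner does not count).
    epsilon:
        Optional buffer applied to each geometry before the intersection
        test, for dirty exports whose boundaries do not line up exactly.
        Default 0 (exact predicate on the input coordinates).
    """
    if rule not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule '{rule}' (use 'queen' or 'rook')")
    if isinstance(polygons, (str, Path)):
        p = Path(polygons)
        if p.exists():
            polygons = json.loads(p.read_text())
        else:
            polygons = json.loads(str(polygons))
    features = polygons.get("features", [])
    if not features:
        raise ValueError("empty GeoJSON feature collection")

    ids: list[str] = []
    geoms = []
    for k, feat in enumerate(features):
        props = feat.get("properties") or {}
        fid = props.get(id_property, feat.get("id"))
        if fid is None:
            raise ValueError(f"feature {k} has no '{id_property}' property")
        fid = str(fid)
        if fid in ids:
            raise ValueError(f"duplicate feature id '{fid}'")
        geom_json = feat.get("geometry")
        if geom_json is None:
            raise ValueError(f"feature '{fid}' has no geometry")
        geom = _shapely_shape(geom_json)
        if geom.is_empty:
            raise ValueError(f"feature '{fid}' has an empty geometry")
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(
                f"feature '{fid}' is a {geom.geom_type}, not a Polygon/MultiPolygon"
            )
        if not geom.is_valid:
            raise ValueError(f"feature '{fid}' has an invalid geometry")
        if epsilon > 0:
            geom = geom.buffer(epsilon)
        ids.append(fid)
        geoms.append(geom)

    m = len(ids)
    tree = shapely.STRtree(geoms)
    edges: set[tuple[int, int]] = set()
    for i in range(m):
        for j in tree.query(geoms[i], predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            if rule == "queen":
                edges.add((i, j))
            else:
                inter = geoms[i].intersection(geoms[j])
                if _geometry_dimension(inter) >= 1:
                    edges.add((i, j))
    return AreaGraph(area_ids=ids, edges=edges)


def build_adjacency_from_edgelist(
    area_ids: Sequence[str], pairs: Iterable[tuple[str, str]]
) -> AreaGraph:
    """Build a contiguity graph from explicit neighbour pairs.

    Duplicate pairs and reversed duplicates collapse to a single edge.
    Every pair member must appear in ``area_ids``.
    """
    ids = [str(a) for a in area_ids]
    index = {a: k for k, a in enumerate(ids)}
    if len(index) != len(ids):
        dupes = sorted({a for a in ids if ids.count(a) > 1})
        raise ValueError(f"duplicate area id(s): {dupes}")
    edges: set[tuple[int, int]] = set()
    for a, b in pairs:
        a, b = str(a), str(b)
        for x in (a, b):
            if x not in index:
                raise ValueError(f"unknown area id '{x}' in neighbour pair ({a}, {b})")
        i, j = index[a], index[b]
        if i == j:
            raise ValueError(f"self-neighbour pair ({a}, {b}) is not allowed")
        edges.add((min(i, j), max(i, j)))
    return AreaGraph(area_ids=ids, edges=edges)


def icar_structure(graph: AreaGraph) -> np.ndarray:
    """Return the ICAR structure matrix Q0 = D - W (dense, m x m)."""
    q = -graph.adjacency_matrix()
    np.fill_diagonal(q, graph.degrees.astype(float))
    return q


def read_edgelist_csv(path) -> list[tuple[str, str]]:
    """Read neighbour pairs from a CSV with columns ``from,to``."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str)
    if not {"from", "to"}.issubset(df.columns):
        raise ValueError("edge-list CSV must have columns 'from' and 'to'")
    return list(zip(df["from"], df["to"]))


def write_edgelist_csv(graph: AreaGraph, path) -> None:
    import pandas as pd

    rows = sorted(
        (graph.area_ids[i], graph.area_ids[j]) for i, j in graph.edges
    )
    pd.DataFrame(rows, columns=["from", "to"]).to_csv(path, index=False)


def component_report(graph: AreaGraph) -> str:
    """Plain-text summary of connected components (islands flagged)."""
    lines = [f"{graph.n_areas} areas, {len(graph.edges)} edges, "
             f"{graph.n_components} connected component(s)"]
    for c, members in enumerate(graph.components()):
        names = [graph.area_ids[i] for i in members]
        tag = "  [island]" if len(members) == 1 else ""
        lines.append(f"component {c}: {len(members)} area(s): {', '.join(names)}{tag}")
    return "\n".join(lines)
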