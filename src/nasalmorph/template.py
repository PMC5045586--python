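"""Reference-template construction: skeleton curves, RDP control points and
anatomical part tags for each slice position.

A template can be built from any reference geometry (a mask stack, or the
synthetic generator's base anatomy); only an approximate skeleton is needed,
since the template's own control-point coordinates are discarded after
registration in favour of the population average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io_alignment import ConfigError, CrossSection
from .labeling import (
    LabelingConfig,
    find_main_branch_point,
    label_branches,
    propagate_curve_labels,
    split_sides,
    _side_graph,
)
from .skeleton import (
    SkeletonEdge,
    SkeletonGraph,
    SkeletonNode,
    resample_polyline,
    skeletonize_section,
)

__all__ = [
    "RDPConfig",
    "ControlPoint",
    "TemplateSlice",
    "rdp_simplify",
    "build_template",
    "write_template",
    "read_template",
]


@dataclass
class RDPConfig:
    """epsilon: characteristic length scale (mm) of the polyline
    simplification; larger epsilon gives fewer control points."""

    epsilon: float = 1.0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be > 0")


def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-24:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def rdp_simplify(curve: np.ndarray, epsilon: float) -> np.ndarray:
    """Ramer-Douglas-Peucker simplification of an ordered point list.

    Recursive farthest-point splitting: the point with the largest
    perpendicular distance to the chord is kept if it exceeds epsilon, and
    the two halves are simplified recursively.  First and last points are
    always kept; when two points are equidistant-farthest the lower index
    wins.  Returns an index-subsequence of the input.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or len(curve) < 2:
        raise ConfigError("RDP needs an ordered list of >= 2 points")
    if epsilon <= 0:
        raise ConfigError("epsilon must be > 0")
    keep = np.zeros(len(curve), dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, len(curve) - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        d = _point_segment_distance(curve[i + 1 : j], curve[i], curve[j])
        k = int(np.argmax(d))  # first maximum -> lower index wins ties
        if d[k] > epsilon:
            mid = i + 1 + k
            keep[mid] = True
            stack.append((i, mid))
            stack.append((mid, j))
    return curve[keep]


def _simplify_edge(poly: np.ndarray, closed: bool, epsilon: float) -> np.ndarray:
    """RDP on an edge polyline; closed loops are split at the point farthest
    from the loop centroid and simplified as an open curve."""
    if closed and len(poly) > 3:
        ring = poly[:-1]
        centroid = ring.mean(axis=0)
        k = int(np.argmax(np.linalg.norm(ring - centroid, axis=1)))
        poly = np.vstack([ring[k:], ring[:k], ring[k : k + 1]])
    return rdp_simplify(poly, epsilon)


@dataclass
class ControlPoint:
    id: int
    edge: int
    arc_s: float  # arc-length parameter along the edge, mm
    xy: np.ndarray  # (x, z) mm
    part: str
    side: str

    def to_json(self):
        return {
            "id": self.id, "edge": self.edge, "arc_s": self.arc_s,
            "xy_mm": [float(self.xy[0]), float(self.xy[1])],
            "part": self.part, "side": self.side,
        }


@dataclass
class TemplateSlice:
    """Reference skeleton + control points + part tags for one slice."""

    y_position: float
    graph: SkeletonGraph | None
    control_points: list[ControlPoint]
    part_tags: dict[int, tuple[str, str]]  # edge id -> (part, side)
    reference_points: np.ndarray  # dense resampled skeleton points, (n, 2) mm
    grid_shape: tuple[int, int]
    pixel_spacing: tuple[float, float]
    extent: tuple[tuple[float, float], tuple[float, float]]
    empty: bool = False

    def control_coordinates(self) -> np.ndarray:
        """Unique control-point coordinates (junctions shared by several
        edges appear once), in stable id order."""
        if not self.control_points:
            return np.zeros((0, 2))
        coords, seen = [], set()
        for cp in self.control_points:
            key = (round(float(cp.xy[0]), 6), round(float(cp.xy[1]), 6))
            if key not in seen:
                seen.add(key)
                coords.append([float(cp.xy[0]), float(cp.xy[1])])
        return np.asarray(coords)

    def blank_section(self) -> CrossSection:
        return CrossSection(
            np.zeros(self.grid_shape, bool), self.pixel_spacing, self.y_position, self.extent
        )


def _edge_part_tags(section: CrossSection, graph: SkeletonGraph, labeling: LabelingConfig):
    """(part, side) per edge of the full-section graph, via the skeleton
    branch rules of the labeling module."""
    tags: dict[int, tuple[str, str]] = {}
    sides = split_sides(section, graph=graph, split_x=labeling.side_split_x)
    for side, side_mask in sides.items():
        if not side_mask.any():
            continue
        g = _side_graph(section, graph, side_mask)
        if not g.edges:
            continue
        point, node_id = find_main_branch_point(g, side)
        if node_id is None:
            labels = {eid: "main" for eid in g.edges}
        else:
            labels = propagate_curve_labels(
                g, label_branches(g, node_id, labeling.branch_cut_radius, side)
            )
        # map side-graph edges back to full-graph edges by pixel membership
        for eid, lab in labels.items():
            pix = set(g.edges[eid].pixels)
            for fid, fe in graph.edges.items():
                if pix & set(fe.pixels):
                    tags.setdefault(fid, (lab, side))
    return tags


def build_template(
    reference_sections: list[CrossSection],
    config: RDPConfig | None = None,
    labeling: LabelingConfig | None = None,
    prune_length: float = 1.5,
    reference_point_spacing: float = 0.86,
) -> list[TemplateSlice]:
    """Build a per-slice template from aligned reference sections.

    Each slice is skeletonized, pruned, labeled, and its edges simplified
    with RDP to produce the control points {X_ij}.  Empty reference slices
    yield template slices marked empty; registration later skips them.
    """
    config = config or RDPConfig()
    labeling = labeling or LabelingConfig()
    slices = []
    for sec in reference_sections:
        shape = sec.shape
        base = dict(
            grid_shape=shape, pixel_spacing=sec.pixel_spacing, extent=sec.extent
        )
        if not sec.mask.any():
            slices.append(
                TemplateSlice(sec.y_position, None, [], {}, np.zeros((0, 2)), empty=True, **base)
            )
            continue
        graph = skeletonize_section(sec, prune_length=prune_length)
        if not graph.edges:
            slices.append(
                TemplateSlice(sec.y_position, graph, [], {}, np.zeros((0, 2)), empty=True, **base)
            )
            continue
        tags = _edge_part_tags(sec, graph, labeling)
        cps: list[ControlPoint] = []
        ref_pts = []
        cid = 0
        for eid in sorted(graph.edges):
            poly = graph.edge_polyline_mm(eid)
            closed = graph.edges[eid].node_ids[0] == graph.edges[eid].node_ids[1]
            simplified = _simplify_edge(poly, closed, config.epsilon)
            seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            s = np.concatenate([[0.0], np.cumsum(seg)])
            part, side = tags.get(eid, ("main", "right"))
            for p in simplified:
                d = np.linalg.norm(poly - p, axis=1)
                arc = float(s[int(np.argmin(d))])
                cps.append(ControlPoint(cid, eid, arc, np.asarray(p, float), part, side))
                cid += 1
            ref_pts.append(resample_polyline(poly, reference_point_spacing))
        slices.append(
            TemplateSlice(
                sec.y_position, graph, cps, tags, np.vstack(ref_pts), empty=False, **base
            )
        )
    return slices


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _graph_to_json(graph: SkeletonGraph) -> dict:
    return {
        "nodes": [{"id": n.id, "rc": list(n.rc), "degree": n.degree} for n in graph.nodes.values()],
        "edges": [
            {"id": e.id, "node_ids": list(e.node_ids), "pixel_chain": [list(p) for p in e.pixels]}
            for e in graph.edges.values()
        ],
        "shape": list(graph.shape),
        "pixel_spacing": list(graph.pixel_spacing),
        "origin_xz": list(graph.origin_xz),
        "y_position": graph.y_position,
    }


def _graph_from_json(doc: dict) -> SkeletonGraph:
    nodes = {n["id"]: SkeletonNode(n["id"], tuple(n["rc"]), n["degree"]) for n in doc["nodes"]}
    edges = {
        e["id"]: SkeletonEdge(e["id"], tuple(e["node_ids"]), [tuple(p) for p in e["pixel_chain"]])
        for e in doc["edges"]
    }
    return SkeletonGraph(
        nodes, edges, tuple(doc["shape"]), tuple(doc["pixel_spacing"]),
        tuple(doc["origin_xz"]), doc["y_position"],
    )


def write_template(path, slices: list[TemplateSlice]) -> None:
    doc = []
    for ts in slices:
        doc.append(
            {
                "y_position": ts.y_position,
                "empty": ts.empty,
                "graph": None if ts.graph is None else _graph_to_json(ts.graph),
                "control_points": [cp.to_json() for cp in ts.control_points],
                "part_tags": {str(k): list(v) for k, v in ts.part_tags.items()},
                "reference_points": ts.reference_points.tolist(),
                "grid_shape": list(ts.grid_shape),
                "pixel_spacing": list(ts.pixel_spacing),
                "extent": [list(ts.extent[0]), list(ts.extent[1])],
            }
        )
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_template(path) -> list[TemplateSlice]:
    with open(path) as fh:
        doc = json.load(fh)
    slices = []
    for d in doc:
        cps = [
            ControlPoint(
                c["id"], c["edge"], c["arc_s"], np.array(c["xy_mm"], float), c["part"], c["side"]
            )
            for c in d["control_points"]
        ]
        slices.append(
            TemplateSlice(
                d["y_position"],
                None if d["graph"] is None else _graph_from_json(d["graph"]),
                cps,
                {int(k): tuple(v) for k, v in d["part_tags"].items()},
                np.array(d["reference_points"], float).reshape(-1, 2),
                tuple(d["grid_shape"]),
                tuple(d["pixel_spacing"]),
                (tuple(d["extent"][0]), tuple(d["extent"][1])),
                d["empty"],
            )
        )
    return slices
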