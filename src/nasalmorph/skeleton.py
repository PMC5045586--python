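"""Medial-axis computation and skeleton-graph decomposition.

The medial axis of each coronal cross-section is computed with Zhang-Suen
thinning (two-subiteration parallel thinning run to convergence), then
decomposed into a graph of endpoints, bifurcation points and curve edges.
Foreground uses 8-connectivity, background 4-connectivity, throughout.

Pixel coordinates are (row, col) with row 0 at the superior image edge; mm
conversions go through the owning cross-section's grid (``origin_xz`` is the
(x_min, z_max) corner, matching ``CrossSection.extent``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_alignment import CrossSection, DEFAULT_PIXEL_SPACING

__all__ = [
    "Skeleton",
    "SkeletonNode",
    "SkeletonEdge",
    "SkeletonGraph",
    "zhang_suen_thin",
    "regularize_skeleton",
    "build_graph",
    "prune_spurs",
    "skeleton_to_pointset",
    "skeletonize_section",
]

# 8-neighbour offsets in clockwise order starting from north (P2..P9 of the
# thinning literature); also the deterministic visiting order for edge tracing.
NEIGHBORS_CW = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass
class Skeleton:
    """One-pixel-wide medial axis of a cross-section."""

    image: np.ndarray  # bool, same shape as the source mask
    pixel_spacing: tuple[float, float]  # (dx, dz) mm
    origin_xz: tuple[float, float] = (0.0, 0.0)  # (x_min, z_max) of the grid
    y_position: float = 0.0

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=bool)

    @property
    def pixels(self) -> np.ndarray:
        return np.argwhere(self.image)

    def rc_to_xz(self, rc) -> np.ndarray:
        rc = np.asarray(rc, dtype=float).reshape(-1, 2)
        dx, dz = self.pixel_spacing
        x0, z1 = self.origin_xz
        return np.column_stack([x0 + (rc[:, 1] + 0.5) * dx, z1 - (rc[:, 0] + 0.5) * dz])


def _neighborhood(img: np.ndarray):
    """The eight shifted copies P2..P9 of a padded binary image."""
    p = np.pad(img, 1).astype(np.uint8)
    shifts = []
    for dr, dc in NEIGHBORS_CW:
        shifts.append(p[1 + dr : p.shape[0] - 1 + dr, 1 + dc : p.shape[1] - 1 + dc])
    return shifts  # order: P2 N, P3 NE, P4 E, P5 SE, P6 S, P7 SW, P8 W, P9 NW


def _crossing_number(shifts) -> np.ndarray:
    """A(p): number of 0->1 transitions in the circular sequence P2..P9,P2."""
    a = np.zeros(shifts[0].shape, dtype=np.uint8)
    for i in range(8):
        a += (shifts[i] == 0) & (shifts[(i + 1) % 8] == 1)
    return a


def zhang_suen_thin(mask: "CrossSection | np.ndarray") -> Skeleton:
    """Zhang-Suen thinning run to convergence.

    Each pass has two parallel subiterations; a pixel is deleted when its
    neighbour count B(p) is in [2, 6], its crossing number A(p) equals 1, and
    the directional products (P2*P4*P6, P4*P6*P8) - respectively
    (P2*P4*P8, P2*P6*P8) in the second subiteration - vanish.
    """
    if isinstance(mask, CrossSection):
        img = mask.mask.copy()
        spacing = mask.pixel_spacing
        origin = (mask.extent[0][0], mask.extent[1][1])
        ypos = mask.y_position
    else:
        img = np.asarray(mask, dtype=bool).copy()
        spacing = (DEFAULT_PIXEL_SPACING, DEFAULT_PIXEL_SPACING)
        origin = (0.0, 0.0)
        ypos = 0.0
    changed = True
    while changed:
        changed = False
        for step in (0, 1):
            s = _neighborhood(img)
            B = sum(x.astype(np.uint8) for x in s)
            A = _crossing_number(s)
            P2, P4, P6, P8 = s[0], s[2], s[4], s[6]
            cond = img & (B >= 2) & (B <= 6) & (A == 1)
            if step == 0:
                cond &= (P2 * P4 * P6 == 0) & (P4 * P6 * P8 == 0)
            else:
                cond &= (P2 * P4 * P8 == 0) & (P2 * P6 * P8 == 0)
            if cond.any():
                img[cond] = False
                changed = True
    return Skeleton(img, spacing, origin, ypos)


def _local_crossing(img, r, c) -> tuple[int, int]:
    """(B, A) of a single pixel (neighbour count and crossing number)."""
    vals = []
    for dr, dc in NEIGHBORS_CW:
        rr, cc = r + dr, c + dc
        vals.append(
            1 if 0 <= rr < img.shape[0] and 0 <= cc < img.shape[1] and img[rr, cc] else 0
        )
    b = sum(vals)
    a = sum(1 for i in range(8) if vals[i] == 0 and vals[(i + 1) % 8] == 1)
    return b, a


# ring-position adjacency: offsets i, j of NEIGHBORS_CW that are 8-adjacent
_RING_ADJ = [
    [
        j
        for j in range(8)
        if i != j
        and max(
            abs(NEIGHBORS_CW[i][0] - NEIGHBORS_CW[j][0]),
            abs(NEIGHBORS_CW[i][1] - NEIGHBORS_CW[j][1]),
        )
        <= 1
    ]
    for i in range(8)
]


def _is_redundant(img, r, c) -> bool:
    """True when the pixel's foreground neighbours stay 8-connected through
    the neighbourhood ring after its removal (a redundant 'simple' pixel)."""
    ring = []
    for i, (dr, dc) in enumerate(NEIGHBORS_CW):
        rr, cc = r + dr, c + dc
        if 0 <= rr < img.shape[0] and 0 <= cc < img.shape[1] and img[rr, cc]:
            ring.append(i)
    if len(ring) < 2:
        return False
    seen = {ring[0]}
    stack = [ring[0]]
    ring_set = set(ring)
    while stack:
        i = stack.pop()
        for j in _RING_ADJ[i]:
            if j in ring_set and j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == len(ring)


def regularize_skeleton(skeleton: Skeleton) -> Skeleton:
    """Remove redundant skeleton pixels (staircase and 2x2-block artifacts).

    Zhang-Suen alone does not guarantee the property that every edge pixel
    has exactly two neighbours and every bifurcation pixel three: diagonal
    staircases leave shortcut adjacencies.  This post-pass deletes, in raster
    order until stable, every non-endpoint pixel whose foreground neighbours
    remain mutually 8-connected without it; topology (components and holes)
    is unchanged because only such 'simple' pixels are removed.
    """
    img = skeleton.image.copy()
    changed = True
    while changed:
        changed = False
        for r, c in np.argwhere(img):
            if _is_redundant(img, r, c):
                img[r, c] = False
                changed = True
    return Skeleton(img, skeleton.pixel_spacing, skeleton.origin_xz, skeleton.y_position)


# ---------------------------------------------------------------------------
# Graph decomposition
# ---------------------------------------------------------------------------


@dataclass
class SkeletonNode:
    id: int
    rc: tuple[int, int]
    degree: int


@dataclass
class SkeletonEdge:
    """An ordered 8-connected pixel chain between two nodes (or a closed loop
    anchored at one node); terminal pixels are the node pixels themselves."""

    id: int
    node_ids: tuple[int, int]
    pixels: list[tuple[int, int]]

    def length_mm(self, spacing: tuple[float, float]) -> float:
        if len(self.pixels) < 2:
            return 0.0
        p = np.asarray(self.pixels, dtype=float)
        d = np.diff(p, axis=0) * np.array([spacing[1], spacing[0]])
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class SkeletonGraph:
    nodes: dict[int, SkeletonNode]
    edges: dict[int, SkeletonEdge]
    shape: tuple[int, int]
    pixel_spacing: tuple[float, float]
    origin_xz: tuple[float, float] = (0.0, 0.0)
    y_position: float = 0.0

    def pixel_set(self) -> set[tuple[int, int]]:
        px = {n.rc for n in self.nodes.values()}
        for e in self.edges.values():
            px.update(e.pixels)
        return px

    def rc_to_xz(self, rc) -> np.ndarray:
        return Skeleton(
            np.zeros((1, 1), bool), self.pixel_spacing, self.origin_xz
        ).rc_to_xz(rc)

    def edge_polyline_mm(self, edge_id: int) -> np.ndarray:
        return self.rc_to_xz(np.asarray(self.edges[edge_id].pixels, dtype=float))

    def to_skeleton(self) -> Skeleton:
        img = np.zeros(self.shape, dtype=bool)
        for r, c in self.pixel_set():
            img[r, c] = True
        return Skeleton(img, self.pixel_spacing, self.origin_xz, self.y_position)

    def incident_edges(self, node_id: int) -> list[int]:
        return [eid for eid, e in self.edges.items() if node_id in e.node_ids]


def build_graph(skeleton: Skeleton) -> SkeletonGraph:
    """Decompose a one-pixel-wide skeleton into nodes and curve edges.

    Pixels with one 8-neighbour are endpoints, with three or more junctions;
    chains of two-neighbour pixels form the edges.  Isolated loops get a
    designated anchor node (their lexicographically smallest pixel).  Edge
    tracing visits neighbours in clockwise order from north, so the
    decomposition is deterministic.
    """
    img = skeleton.image
    fg = np.argwhere(img)
    deg = {}
    for r, c in fg:
        b, _ = _local_crossing(img, r, c)
        deg[(r, c)] = b
    node_px = sorted(p for p, d in deg.items() if d != 2)
    nodes = {}
    node_id_of = {}
    for i, p in enumerate(node_px):
        nodes[i] = SkeletonNode(i, (int(p[0]), int(p[1])), deg[p])
        node_id_of[p] = i

    edges: dict[int, SkeletonEdge] = {}
    used_dirs: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    eid = 0

    def neighbors_of(p):
        out = []
        for dr, dc in NEIGHBORS_CW:
            q = (p[0] + dr, p[1] + dc)
            if 0 <= q[0] < img.shape[0] and 0 <= q[1] < img.shape[1] and img[q]:
                out.append(q)
        return out

    for p in node_px:
        for q in neighbors_of(p):
            if (p, q) in used_dirs:
                continue
            chain = [p, q]
            used_dirs.add((p, q))
            prev, cur = p, q
            while cur not in node_id_of:
                nxt = [n for n in neighbors_of(cur) if n != prev]
                # a degree-2 pixel has exactly one forward neighbour, except
                # tight turns where prev is 8-adjacent to next; take first in
                # clockwise order not yet walked
                step = None
                for n in nxt:
                    if (cur, n) not in used_dirs:
                        step = n
                        break
                if step is None:
                    break
                used_dirs.add((cur, step))
                chain.append(step)
                prev, cur = cur, step
            if cur in node_id_of:
                used_dirs.add((cur, prev))
                edges[eid] = SkeletonEdge(
                    eid, (node_id_of[p], node_id_of[cur]), [tuple(map(int, x)) for x in chain]
                )
                eid += 1

    covered = {n.rc for n in nodes.values()}
    for e in edges.values():
        covered.update(e.pixels)
    remaining = sorted(set(map(tuple, fg.tolist())) - covered)
    # isolated closed loops: every pixel degree 2 and unreached from any node
    visited = set()
    for p in remaining:
        if p in visited:
            continue
        anchor = p
        chain = [anchor]
        visited.add(anchor)
        prev, cur = anchor, None
        for n in neighbors_of(anchor):
            cur = n
            break
        while cur is not None and cur != anchor:
            chain.append(cur)
            visited.add(cur)
            nxt = [n for n in neighbors_of(cur) if n != prev and (n == anchor or n not in visited)]
            if not nxt:
                cur = anchor
                break
            prev, cur = cur, nxt[0]
        nid = len(nodes)
        nodes[nid] = SkeletonNode(nid, (int(anchor[0]), int(anchor[1])), deg.get(anchor, 0))
        chain = [tuple(map(int, x)) for x in chain] + [tuple(map(int, anchor))]
        if len(chain) > 2:
            edges[eid] = SkeletonEdge(eid, (nid, nid), chain)
            eid += 1
    return SkeletonGraph(
        nodes, edges, img.shape, skeleton.pixel_spacing, skeleton.origin_xz, skeleton.y_position
    )


def prune_spurs(graph: SkeletonGraph, min_length: float) -> SkeletonGraph:
    """Iteratively remove leaf edges shorter than ``min_length`` mm.

    Only spurs attached to a junction are removed (an isolated short segment
    is a component of its own and is kept), so connectivity is preserved.
    Former junctions that drop to degree two are merged into their
    neighbouring edges by rebuilding the graph.  Idempotent at fixed length.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    g = graph
    while True:
        removed = False
        img = g.to_skeleton().image
        for e in g.edges.values():
            n0, n1 = (g.nodes[i] for i in e.node_ids)
            if e.node_ids[0] == e.node_ids[1]:
                continue
            leaf, junction = None, None
            if n0.degree == 1 and n1.degree >= 3:
                leaf, junction = n0, n1
            elif n1.degree == 1 and n0.degree >= 3:
                leaf, junction = n1, n0
            if leaf is None:
                continue
            if e.length_mm(g.pixel_spacing) < min_length:
                for px in e.pixels:
                    if px != junction.rc:
                        img[px] = False
                removed = True
        if not removed:
            return g
        # re-regularize: removing a spur can leave a redundant stub pixel
        # hanging on the surviving curve (diagonal attachments)
        g = build_graph(
            regularize_skeleton(Skeleton(img, g.pixel_spacing, g.origin_xz, g.y_position))
        )


def skeleton_to_pointset(graph: SkeletonGraph, spacing: float) -> dict[int, np.ndarray]:
    """Arc-length resample every edge at ``spacing`` mm; endpoints always kept.

    Returns a map edge id -> (n, 2) array of (x, z) mm points.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    out = {}
    for eid, e in graph.edges.items():
        poly = graph.edge_polyline_mm(eid)
        out[eid] = resample_polyline(poly, spacing)
    return out


def resample_polyline(poly: np.ndarray, spacing: float) -> np.ndarray:
    """Equally spaced (in arc length) points along a polyline, endpoints kept."""
    poly = np.asarray(poly, dtype=float)
    if len(poly) < 2:
        return poly.copy()
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return poly[[0, -1]].copy()
    n = max(2, int(round(total / spacing)) + 1)
    t = np.linspace(0.0, total, n)
    x = np.interp(t, s, poly[:, 0])
    z = np.interp(t, s, poly[:, 1])
    return np.column_stack([x, z])


def skeletonize_section(
    section: CrossSection, prune_length: float = 1.5
) -> SkeletonGraph:
    """Full per-section skeleton pipeline: thin, regularize, graph, prune."""
    skel = regularize_skeleton(zhang_suen_thin(section))
    graph = build_graph(skel)
    if prune_length > 0:
        graph = prune_spurs(graph, prune_length)
    return graph
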