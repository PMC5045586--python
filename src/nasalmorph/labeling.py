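"""Automated per-passage labeling and cross-sectional-area profiling.

Each side of a coronal section is split into inferior / middle / superior
passages based on the skeleton: the main branch point (where the middle
turbinate branches from the main passage) is located, the three skeletal
branches from it are cut off at r = 3 mm to remove ambiguity near the
junction, and direction rules label the branches.  Remaining skeleton curves
inherit labels by greedy nearest-endpoint propagation, and mask pixels by
greedy nearest-labeled-pixel growth - the growth order matters, which is why
a naive nearest-curve assignment is not used.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_alignment import ConfigError, CrossSection, PipelineError
from .skeleton import Skeleton, SkeletonGraph, build_graph, skeletonize_section

__all__ = [
    "LabelingConfig",
    "LabeledSection",
    "AmbiguousBranchError",
    "LABEL_CODES",
    "split_sides",
    "find_main_branch_point",
    "label_branches",
    "propagate_curve_labels",
    "propagate_pixel_labels",
    "label_section",
    "csa_profile",
]

LABEL_CODES = {"inferior": 1, "middle": 2, "superior": 3, "main": 4, "supreme": 5}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}
SIDE_OFFSET = {"right": 0, "left": 10}


class AmbiguousBranchError(PipelineError):
    """The branch point does not offer three usable branches to label."""


@dataclass
class LabelingConfig:
    """branch_cut_radius: arc length (mm) excluded from the direction test
    around the branch point (default 3, following the branch-cut rule);
    ``separate_supreme`` reports a fourth, supreme label instead of folding it
    into superior; ``side_split_x`` overrides the automatic side split."""

    branch_cut_radius: float = 3.0
    separate_supreme: bool = False
    side_split_x: float | None = None
    prune_length: float = 1.5

    def __post_init__(self):
        if self.branch_cut_radius <= 0:
            raise ConfigError("branch_cut_radius must be > 0")


@dataclass
class LabeledSection:
    """Per-pixel passage labels for one cross-section.

    Codes: 1 inferior, 2 middle, 3 superior, 4 main, 5 supreme; +10 for the
    left side; 0 background.  Labels partition the mask exactly.
    """

    label_image: np.ndarray
    pixel_spacing: tuple[float, float]
    y_position: float
    branch_points: dict[str, np.ndarray | None] = field(default_factory=dict)

    def counts(self) -> dict[int, int]:
        vals, cnt = np.unique(self.label_image[self.label_image > 0], return_counts=True)
        return dict(zip(map(int, vals), map(int, cnt)))


# ---------------------------------------------------------------------------
# Side separation
# ---------------------------------------------------------------------------


def split_sides(
    section: CrossSection, graph: SkeletonGraph | None = None, split_x: float | None = None
) -> dict[str, np.ndarray]:
    """Split the mask into right (x < septum) and left passage masks.

    When the septum fully separates the passages, connected components are
    assigned by centroid side.  A component spanning both sides is split at
    the x of the skeleton curve lying nearest the midline (or at ``split_x``).
    """
    mask = section.mask
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    right = np.zeros_like(mask)
    left = np.zeros_like(mask)
    if n == 0:
        return {"right": right, "left": left}
    x_centers = section.pixel_to_xz(
        np.column_stack([np.zeros(mask.shape[1]), np.arange(mask.shape[1])])
    )[:, 0]
    if n == 1 or split_x is not None:
        xs = x_centers[np.any(mask, axis=0)]
        if split_x is None and not (xs.min() < -2.0 and xs.max() > 2.0):
            # the whole mask sits on one side of the midline
            com = ndimage.center_of_mass(mask)
            if x_centers[int(round(com[1]))] < 0:
                return {"right": mask.copy(), "left": left}
            return {"right": right, "left": mask.copy()}
        # a deviated septum that does not separate the passages: split at the
        # skeleton curve nearest the midline (or at the configured x)
        sx = split_x
        if sx is None and n == 1:
            g = graph or skeletonize_section(section)
            best = None
            for eid in g.edges:
                ex = np.abs(g.edge_polyline_mm(eid)[:, 0]).mean()
                if best is None or ex < best[0]:
                    best = (ex, float(g.edge_polyline_mm(eid)[:, 0].mean()))
            sx = best[1] if best else 0.0
        sx = 0.0 if sx is None else sx
        right = mask & (x_centers[None, :] < sx)
        left = mask & (x_centers[None, :] >= sx)
        return {"right": right, "left": left}
    # separated passages: the two largest components are the passages, told
    # apart by relative position (a deviated septum can push one across x=0);
    # smaller fragments (congestion remnants) join the nearest passage
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    cx = []
    for i in order[:2]:
        com = ndimage.center_of_mass(lab == i)
        cx.append(x_centers[int(round(com[1]))])
    if len(cx) == 2 and cx[0] > cx[1]:
        right_id, left_id = order[1], order[0]
    else:
        right_id, left_id = order[0], (order[1] if len(order) > 1 else None)
    right |= lab == right_id
    if left_id is not None:
        left |= lab == left_id
    from scipy.spatial import cKDTree

    rc_mm = lambda m: section.pixel_to_xz(np.argwhere(m).astype(float))
    trees = {"right": cKDTree(rc_mm(right))}
    if left.any():
        trees["left"] = cKDTree(rc_mm(left))
    for i in order[2:]:
        comp = lab == i
        pts = rc_mm(comp)
        d = {s: t.query(pts)[0].min() for s, t in trees.items()}
        if d.get("left", np.inf) < d["right"]:
            left |= comp
        else:
            right |= comp
    return {"right": right, "left": left}


# ---------------------------------------------------------------------------
# Branch decomposition and direction rules
# ---------------------------------------------------------------------------


def _branch_decomposition(graph: SkeletonGraph, junction_id: int):
    """Assign every edge reachable from the junction to one incident branch.

    Dijkstra over graph nodes seeded through each incident edge; cycle edges
    go to the branch that reaches them first (shorter arc length, then lower
    branch index).  Returns for each branch the list of (xz, arc_dist) pixel
    samples and its maximal arc length.
    """
    spacing = graph.pixel_spacing
    J = graph.nodes[junction_id]
    incident = sorted(graph.incident_edges(junction_id))
    branches = {b: [] for b in range(len(incident))}
    edge_branch: dict[int, int] = {}
    node_dist: dict[int, float] = {junction_id: 0.0}
    heap = []
    for b, eid in enumerate(incident):
        e = graph.edges[eid]
        other = e.node_ids[1] if e.node_ids[0] == junction_id else e.node_ids[0]
        heapq.heappush(heap, (e.length_mm(spacing), b, other, eid, junction_id))
    visited = set()
    while heap:
        d, b, node, eid, from_node = heapq.heappop(heap)
        if eid not in edge_branch:
            edge_branch[eid] = b
            e = graph.edges[eid]
            px = e.pixels if e.node_ids[0] == from_node else e.pixels[::-1]
            xz = graph.rc_to_xz(np.asarray(px, float))
            seg = np.linalg.norm(np.diff(xz, axis=0), axis=1)
            arc = node_dist.get(from_node, d) + np.concatenate([[0.0], np.cumsum(seg)])
            branches[b].append((px, xz, arc))
        if node in visited or node == junction_id:
            continue
        visited.add(node)
        node_dist[node] = min(node_dist.get(node, np.inf), d)
        for eid2 in sorted(graph.incident_edges(node)):
            if eid2 in edge_branch or eid2 == eid:
                continue
            e2 = graph.edges[eid2]
            other = e2.node_ids[1] if e2.node_ids[0] == node else e2.node_ids[0]
            heapq.heappush(heap, (d + e2.length_mm(spacing), b, other, eid2, node))
    edges_by_branch = {b: [e for e, bb in edge_branch.items() if bb == b] for b in branches}
    return branches, edges_by_branch


def _branch_stats(samples, r_cut: float):
    """min z, directional x extrema and max arc length beyond the cut."""
    all_xz, all_arc = [], []
    for _px, xz, arc in samples:
        all_xz.append(xz)
        all_arc.append(arc)
    if not all_xz:
        return None
    xz = np.vstack(all_xz)
    arc = np.concatenate(all_arc)
    far = arc > r_cut
    if not far.any():
        far = arc >= arc.max() - 1e-9  # branch shorter than the cut: use its tip
    return {
        "min_z": float(xz[far, 1].min()),
        "min_x": float(xz[far, 0].min()),
        "max_x": float(xz[far, 0].max()),
        "length": float(arc.max()),
    }


def _direction_labels(stats: dict[int, dict], side: str):
    """Sequential direction rules on the three longest branches: the branch
    reaching the most negative z is inferior; of the remaining two, the one
    reaching the most negative x (right side; sign flipped on the left) is
    middle; the last is superior.  (Applying the two criteria independently
    can select the same branch when an inferior meatus hooks far laterally
    under a strongly deviated septum.)"""
    longest = sorted(stats, key=lambda b: -stats[b]["length"])[:3]
    if len(longest) < 3:
        return None
    inferior = min(longest, key=lambda b: (stats[b]["min_z"], b))
    rest = [b for b in longest if b != inferior]
    if side == "right":
        middle = min(rest, key=lambda b: (stats[b]["min_x"], b))
    else:
        middle = min(rest, key=lambda b: (-stats[b]["max_x"], b))
    superior = next(b for b in rest if b != middle)
    return {inferior: "inferior", middle: "middle", superior: "superior"}


def find_main_branch_point(graph: SkeletonGraph, side: str):
    """Locate the main branch point of one side's skeleton.

    Candidate junctions are evaluated bottom-up (most negative z first) -
    anatomically the middle turbinate is the lowest branching off the main
    passage - and the first offering three usable branches wins.  Returns
    (xz point, node id) or (None, None) when the side has no junction (e.g.
    posterior slices without a superior meatus).
    """
    junctions = [n for n in graph.nodes.values() if n.degree >= 3]
    junctions.sort(key=lambda n: (graph.rc_to_xz([n.rc])[0, 1], n.rc))
    for node in junctions:
        branches, _ = _branch_decomposition(graph, node.id)
        stats = {
            b: s
            for b in branches
            if (s := _branch_stats(branches[b], 3.0)) is not None
        }
        if len(stats) < 3:
            continue
        if _direction_labels(stats, side) is not None:
            return graph.rc_to_xz([node.rc])[0], node.id
    return None, None


def label_branches(
    graph: SkeletonGraph, branch_point_id: int, r_cut: float, side: str
) -> dict[int, str]:
    """Initial edge labels from the direction rules at the chosen junction.

    The first ``r_cut`` mm of each incident branch are excluded from the
    direction test; the branch reaching the most negative z is inferior, the
    one reaching the most negative x (right side; sign flipped on the left)
    is middle, and the remaining of the three longest is superior.
    """
    branches, edges_by_branch = _branch_decomposition(graph, branch_point_id)
    stats = {
        b: s for b in branches if (s := _branch_stats(branches[b], r_cut)) is not None
    }
    if len(stats) < 3:
        raise AmbiguousBranchError("branch point has fewer than three usable branches")
    labels = _direction_labels(stats, side)
    if labels is None:
        raise AmbiguousBranchError("could not resolve three branch directions")
    edge_labels: dict[int, str] = {}
    for b, lab in labels.items():
        for eid in edges_by_branch[b]:
            edge_labels[eid] = lab
    return edge_labels


def propagate_curve_labels(
    graph: SkeletonGraph, edge_labels: dict[int, str]
) -> dict[int, str]:
    """Greedy label propagation between curves.

    Repeatedly pick the unlabeled curve with an endpoint closest (Euclidean
    mm) to any labeled curve's pixels and give it that curve's label; ties by
    the candidate endpoint's (row, col), then the anchor pixel's.
    """
    labels = dict(edge_labels)
    unlabeled = [eid for eid in graph.edges if eid not in labels]
    if not labels and unlabeled:
        raise PipelineError("no labeled curve to propagate from")
    while unlabeled:
        best = None
        for eid in unlabeled:
            pts = graph.edges[eid].pixels
            endpoints = [pts[0], pts[-1]]
            for ep in endpoints:
                ep_xz = graph.rc_to_xz([ep])[0]
                for aid, lab in labels.items():
                    apx = np.asarray(graph.edges[aid].pixels)
                    axz = graph.rc_to_xz(apx.astype(float))
                    d = np.linalg.norm(axz - ep_xz, axis=1)
                    k = int(np.argmin(d))
                    key = (float(d[k]), tuple(ep), tuple(apx[k]), eid)
                    if best is None or key < best[0]:
                        best = (key, eid, lab)
        _, eid, lab = best
        labels[eid] = lab
        unlabeled.remove(eid)
    return labels


def propagate_pixel_labels(
    mask: np.ndarray,
    skeleton_labels: np.ndarray,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Label every mask pixel by greedy growth from the labeled skeleton.

    At each step the unlabeled mask pixel closest (Euclidean mm between pixel
    centers) to the current labeled set takes the label of its nearest
    labeled pixel; the labeled set then grows by that pixel.  Candidate ties
    break by the candidate's (row, col); among equidistant anchors the one
    that first attained that distance wins (initial skeleton anchors in
    lexicographic order) - a purely lexicographic anchor rule would let a
    label front creep along a channel wall into a neighbouring passage.
    Exactly equivalent to the literal one-at-a-time greedy procedure,
    implemented with incremental nearest-anchor updates.
    """
    mask = np.asarray(mask, dtype=bool)
    skeleton_labels = np.asarray(skeleton_labels)
    if not (skeleton_labels > 0).any():
        raise PipelineError("empty labeled skeleton")
    if ((skeleton_labels > 0) & ~mask).any():
        raise PipelineError("labeled skeleton must lie inside the mask")
    dx, dz = float(pixel_spacing[0]), float(pixel_spacing[1])
    out = np.where(mask, skeleton_labels, 0).astype(np.int16)
    todo = np.argwhere(mask & (out == 0))
    anchors = np.argwhere(out > 0)
    if not len(todo):
        return out
    order = np.lexsort((anchors[:, 1], anchors[:, 0]))
    anchors = anchors[order]

    tr = todo[:, 0].astype(float)
    tc = todo[:, 1].astype(float)
    d2 = ((tr[:, None] - anchors[None, :, 0]) * dz) ** 2 + (
        (tc[:, None] - anchors[None, :, 1]) * dx
    ) ** 2
    k = np.argmin(d2, axis=1)  # first minimum = lexicographically smallest anchor
    best_d2 = d2[np.arange(len(todo)), k]
    best_anchor = anchors[k]

    active = np.ones(len(todo), dtype=bool)
    n_left = len(todo)
    while n_left:
        idx = np.flatnonzero(active)
        d = best_d2[idx]
        m = d.min()
        cand = idx[d == m]
        if len(cand) > 1:
            key = np.lexsort((todo[cand, 1], todo[cand, 0]))
            chosen = cand[key[0]]
        else:
            chosen = cand[0]
        r, c = todo[chosen]
        ar, ac = best_anchor[chosen]
        out[r, c] = out[ar, ac]
        active[chosen] = False
        n_left -= 1
        if n_left:
            idx = np.flatnonzero(active)
            nd2 = ((todo[idx, 0] - r) * dz) ** 2 + ((todo[idx, 1] - c) * dx) ** 2
            better = nd2 < best_d2[idx]  # strict: on ties the earlier anchor stays
            upd = idx[better]
            best_d2[upd] = nd2[better]
            best_anchor[upd] = (r, c)
    return out


# ---------------------------------------------------------------------------
# Full-section driver and CSA profiles
# ---------------------------------------------------------------------------


def _side_graph(section: CrossSection, graph: SkeletonGraph, side_mask: np.ndarray) -> SkeletonGraph:
    img = np.zeros(section.shape, dtype=bool)
    for r, c in graph.pixel_set():
        img[r, c] = True
    img &= side_mask
    skel = Skeleton(
        img, section.pixel_spacing, (section.extent[0][0], section.extent[1][1]), section.y_position
    )
    return build_graph(skel)


def _relabel_supreme(graph: SkeletonGraph, labels: dict[int, str]) -> dict[int, str]:
    """Optionally split the supreme meatus out of the superior label: at the
    topmost junction inside the superior subgraph, the branch reaching the
    highest z is relabeled supreme."""
    sup_edges = [eid for eid, lab in labels.items() if lab == "superior"]
    sub_nodes = set()
    for eid in sup_edges:
        sub_nodes.update(graph.edges[eid].node_ids)
    junctions = [
        n for n in graph.nodes.values() if n.id in sub_nodes and n.degree >= 3
    ]
    if not junctions:
        return labels
    top = max(junctions, key=lambda n: (graph.rc_to_xz([n.rc])[0, 1], tuple(-v for v in n.rc)))
    branches, edges_by_branch = _branch_decomposition(graph, top.id)
    best_b, best_z = None, -np.inf
    for b, samples in branches.items():
        eids = edges_by_branch[b]
        if not all(labels.get(e) == "superior" for e in eids):
            continue
        zmax = max(float(xz[:, 1].max()) for _p, xz, _a in samples)
        if zmax > best_z:
            best_b, best_z = b, zmax
    if best_b is not None:
        for eid in edges_by_branch[best_b]:
            labels[eid] = "supreme"
    return labels


def label_section(
    section: CrossSection,
    config: LabelingConfig | None = None,
    graph: SkeletonGraph | None = None,
) -> LabeledSection:
    """Label both sides of a section and return the per-pixel label image."""
    config = config or LabelingConfig()
    if graph is None:
        graph = skeletonize_section(section, prune_length=config.prune_length)
    sides = split_sides(section, graph=graph, split_x=config.side_split_x)
    label_image = np.zeros(section.shape, dtype=np.int16)
    branch_points: dict[str, np.ndarray | None] = {}
    for side, side_mask in sides.items():
        if not side_mask.any():
            branch_points[side] = None
            continue
        g = _side_graph(section, graph, side_mask)
        if not g.edges:
            branch_points[side] = None
            # mask without skeleton curves (tiny blob): label as main
            label_image[side_mask] = LABEL_CODES["main"] + SIDE_OFFSET[side]
            continue
        point, node_id = find_main_branch_point(g, side)
        branch_points[side] = point
        if node_id is None:
            edge_labels = {eid: "main" for eid in g.edges}
        else:
            edge_labels = label_branches(g, node_id, config.branch_cut_radius, side)
            edge_labels = propagate_curve_labels(g, edge_labels)
            if config.separate_supreme:
                edge_labels = _relabel_supreme(g, edge_labels)
        skel_labels = np.zeros(section.shape, dtype=np.int16)
        for eid in sorted(g.edges, reverse=True):
            code = LABEL_CODES[edge_labels[eid]]
            for r, c in g.edges[eid].pixels:
                skel_labels[r, c] = code  # shared node pixels: smallest edge id wins
        skel_labels[~side_mask] = 0
        side_labels = propagate_pixel_labels(side_mask, skel_labels, section.pixel_spacing)
        label_image[side_mask] = side_labels[side_mask] + SIDE_OFFSET[side]
    return LabeledSection(label_image, section.pixel_spacing, section.y_position, branch_points)


def csa_profile(labeled_sections: list[LabeledSection]) -> pd.DataFrame:
    """Per-slice, per-side, per-label cross-sectional areas in mm^2.

    Includes a 'total' row per (slice, side); per-label areas sum exactly to
    the totals because the labels partition each mask.
    """
    rows = []
    for sec in labeled_sections:
        px_area = sec.pixel_spacing[0] * sec.pixel_spacing[1]
        counts = sec.counts()
        for side, off in SIDE_OFFSET.items():
            total = 0
            for code, name in CODE_LABELS.items():
                n = counts.get(code + off, 0)
                total += n
                if n:
                    rows.append(
                        {"y_mm": sec.y_position, "side": side, "label": name,
                         "area_mm2": n * px_area}
                    )
            rows.append(
                {"y_mm": sec.y_position, "side": side, "label": "total",
                 "area_mm2": total * px_area}
            )
    return pd.DataFrame(rows, columns=["y_mm", "side", "label", "area_mm2"])
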