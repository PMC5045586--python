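"""Independent reference implementations used as test oracles.

These are deliberately naive, loop-based transcriptions kept separate from
the package's vectorized implementations: the thinning rules as published,
the greedy label-propagation procedures one pixel / one curve at a time, and
a dense thin-plate-spline solve.
"""

from __future__ import annotations

import numpy as np

# neighbour order P2..P9: N, NE, E, SE, S, SW, W, NW
_P_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def zhang_suen_reference(mask: np.ndarray) -> np.ndarray:
    """Literal two-subiteration Zhang-Suen thinning, parallel deletion."""
    img = np.asarray(mask, dtype=bool).copy()
    rows, cols = img.shape

    def p(r, c, i):
        dr, dc = _P_OFFSETS[i]
        rr, cc = r + dr, c + dc
        return 1 if 0 <= rr < rows and 0 <= cc < cols and img[rr, cc] else 0

    changed = True
    while changed:
        changed = False
        for step in (0, 1):
            deletions = []
            # only foreground pixels are deletion candidates
            for r, c in map(tuple, np.argwhere(img)):
                vals = [p(r, c, i) for i in range(8)]
                B = sum(vals)
                if not (2 <= B <= 6):
                    continue
                A = sum(1 for i in range(8) if vals[i] == 0 and vals[(i + 1) % 8] == 1)
                if A != 1:
                    continue
                P2, P4, P6, P8 = vals[0], vals[2], vals[4], vals[6]
                if step == 0:
                    if P2 * P4 * P6 == 0 and P4 * P6 * P8 == 0:
                        deletions.append((r, c))
                else:
                    if P2 * P4 * P8 == 0 and P2 * P6 * P8 == 0:
                        deletions.append((r, c))
            for r, c in deletions:
                img[r, c] = False
            if deletions:
                changed = True
    return img


def greedy_pixel_labels_reference(
    mask: np.ndarray, skeleton_labels: np.ndarray, pixel_spacing=(1.0, 1.0)
) -> np.ndarray:
    """Literal greedy growth: repeatedly label the unlabeled mask pixel
    closest to the labeled set (candidate ties by (row, col); among
    equidistant anchors the earliest-labeled wins, initial anchors in
    lexicographic order)."""
    mask = np.asarray(mask, bool)
    out = np.where(mask, np.asarray(skeleton_labels), 0).astype(int)
    dx, dz = float(pixel_spacing[0]), float(pixel_spacing[1])
    anchor_order = [tuple(p) for p in np.argwhere(out > 0)]  # lex order
    todo = {tuple(p) for p in np.argwhere(mask & (out == 0))}
    while todo:
        best = None
        for r, c in sorted(todo):
            bd, blab = None, None
            for ar, ac in anchor_order:
                d = ((r - ar) * dz) ** 2 + ((c - ac) * dx) ** 2
                if bd is None or d < bd:  # strict: earliest anchor keeps ties
                    bd, blab = d, out[ar, ac]
            if best is None or (bd, r, c) < best[0]:
                best = ((bd, r, c), (r, c), blab)
        _, (r, c), lab = best
        out[r, c] = lab
        anchor_order.append((r, c))
        todo.remove((r, c))
    return out


def greedy_curve_labels_reference(curves: dict, labels: dict) -> dict:
    """Literal greedy curve propagation.

    ``curves``: id -> (n, 2) array of point coordinates (mm), first and last
    rows being the endpoints; ``labels``: id -> label for the seeded subset.
    """
    labels = dict(labels)
    todo = [cid for cid in curves if cid not in labels]
    while todo:
        best = None
        for cid in todo:
            pts = curves[cid]
            for ep in (pts[0], pts[-1]):
                for aid, lab in labels.items():
                    for ap in curves[aid]:
                        d = float(np.hypot(*(ap - ep)))
                        key = (d, tuple(ep), tuple(ap), cid)
                        if best is None or key < best[0]:
                            best = (key, cid, lab)
        _, cid, lab = best
        labels[cid] = lab
        todo.remove(cid)
    return labels


def tps_dense_reference(x: np.ndarray, y: np.ndarray):
    """Dense TPS interpolation solve with the raw (unnormalized) system.

    Returns (w, affine_coeffs, bending_energy); kernel U(r) = r^2 log r^2.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            r2 = np.sum((x[i] - x[j]) ** 2)
            K[i, j] = r2 * np.log(r2) if r2 > 0 else 0.0
    P = np.column_stack([np.ones(n), x])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = y
    sol = np.linalg.solve(A, rhs)
    w = sol[:n]
    energy = float(np.sum(w * (K @ w)))
    return w, sol[n:], energy


def point_polyline_distance(p: np.ndarray, poly: np.ndarray) -> float:
    """Distance from a point to a polyline (minimum over its segments)."""
    best = np.inf
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
        best = min(best, float(np.linalg.norm(p - (a + t * ab))))
    return best
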