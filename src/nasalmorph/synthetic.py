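"""Parametric nasal-cavity-like cross-sections with full ground truth.

The generator emulates the anatomy and its population variation: two
passages separated by a (possibly deviated) septum, each a near-vertical
main channel with an inferior hook and laterally curving middle / superior
(and optionally supreme) meatuses, swept with part-specific width profiles.
Congestion events close off sub-regions, which can split a passage into
several closed boundaries.  Every section carries ground truth: centerline
polylines per part, branch points, a part-label image, and - for population
scans - the exact TPS warp that produced them.

Populations are built as zero-mean truncated-Gaussian TPS warps of one base
anatomy, so the population mean shape equals the base shape and "does the
pipeline's average recover the base?" is a well-posed recovery test.  The
default cohort size is 26 scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_alignment import (
    ConfigError,
    CrossSection,
    LandmarkPair,
    PipelineError,
    VolumeMask,
    make_grid,
)
from .registration import TPSTransform, tps_fit

__all__ = ["SynthParams", "GroundTruth", "Scan", "Population",
           "make_section", "make_population", "make_volume"]

PART_CODES = {"inferior": 1, "middle": 2, "superior": 3, "main": 4}
SIDE_OFFSET = {"right": 0, "left": 10}


@dataclass
class SynthParams:
    """Generator configuration (all lengths in mm).

    n_meatus : 3 or 4 passages per side (4 adds a supreme meatus).
    septum_deviation : amplitude of the lateral septum bow.
    half_widths : per-part channel half-widths at their widest.
    congestion : list of (side, part, (a0, a1)) arc-fraction intervals where
        the channel width collapses to zero.
    warp_magnitude : maximum control-point displacement of population warps.
    population_size : number of pseudo-scans (cohort size).
    """

    seed: int = 0
    n_meatus: int = 3
    septum_deviation: float = 2.0
    half_widths: dict = field(
        default_factory=lambda: {
            "main": 1.5, "inferior": 1.6, "middle": 1.0, "superior": 0.9, "supreme": 0.8
        }
    )
    congestion: list = field(default_factory=list)
    # 112 x 112 pixels at scan resolution, symmetric about the septum plane
    extent: tuple = ((-24.08, 24.08), (0.0, 48.16))
    pixel_spacing: float = 0.43
    y_positions: tuple = (18.0, 24.0, 30.0, 36.0, 42.0, 48.0)
    warp_magnitude: float = 2.0
    width_jitter: float = 0.0
    population_size: int = 26

    def __post_init__(self):
        if self.n_meatus not in (3, 4):
            raise ConfigError("n_meatus must be 3 or 4")
        if any(w < 0 for w in self.half_widths.values()):
            raise ConfigError("half-widths must be >= 0")
        if self.warp_magnitude < 0 or self.population_size < 1:
            raise ConfigError("invalid population parameters")


@dataclass
class GroundTruth:
    """Per-section ground truth for testing the pipeline stages."""

    centerlines: dict  # (side, part) -> (n, 2) polyline, mm
    half_width: dict  # (side, part) -> (n,) half-widths along the polyline
    branch_points: dict  # side -> (x, z) or None
    label_image: np.ndarray  # part codes (+10 left), 0 background
    warp: TPSTransform | None = None


@dataclass
class Scan:
    sections: list[CrossSection]
    truths: list[GroundTruth]
    landmarks: LandmarkPair


@dataclass
class Population:
    base_sections: list[CrossSection]
    base_truths: list[GroundTruth]
    scans: list[Scan]
    y_positions: tuple


def _bezier(p0, p1, p2, n=60) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, float) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _y_profile(y: float, y_peak: float, width: float = 22.0, floor: float = 0.55) -> float:
    """Smooth rise-peak-decline factor along the airway axis."""
    return floor + (1.0 - floor) * float(np.exp(-((y - y_peak) / width) ** 2 * 4.0))


def _side_curves(params: SynthParams, y: float, side: str):
    """Centerline polylines and half-width arrays for one side at position y."""
    s = 1.0 if side == "left" else -1.0
    z0, z1 = 7.0, 38.0 + 2.0 * np.sin(y / 60.0 * np.pi)
    dev = params.septum_deviation * np.sin(np.pi * y / 60.0)

    def septum_x(z):
        return dev * np.sin(np.pi * (z - z0) / (z1 - z0))

    gap = 2.2
    z_mid = 19.0 + 2.0 * (y - 30.0) / 30.0
    z_sup = 29.0 + 1.5 * (y - 30.0) / 30.0
    lat = 1.0 + 0.3 * np.sin(np.pi * y / 60.0)  # lateral reach factor

    curves: dict[str, np.ndarray] = {}
    zc = np.linspace(z0, z1, 80)
    main = np.column_stack([septum_x(zc) + s * gap, zc])
    # inferior hook at the channel bottom, curving laterally toward the floor
    hook = _bezier(
        [main[0, 0], z0], [main[0, 0] + s * 3.0 * lat, z0 - 0.8], [main[0, 0] + s * 7.0 * lat, z0 - 1.8], 30
    )
    inferior_pts = np.vstack([hook[::-1], main[zc <= z_mid][1:]])
    curves["inferior"] = inferior_pts
    curves["superior_main"] = main[zc > z_mid]

    def on_main(z):
        return np.array([septum_x(z) + s * gap, z])

    m0 = on_main(z_mid)
    curves["middle"] = _bezier(
        m0, m0 + [s * 6.0 * lat, 1.2], m0 + [s * (9.5 + 1.5 * lat), -2.5], 45
    )
    p0 = on_main(z_sup)
    curves["superior"] = _bezier(p0, p0 + [s * 4.0 * lat, 3.5], p0 + [s * 6.5 * lat, 6.5], 35)
    if params.n_meatus >= 4 and y >= 24.0:
        q0 = on_main(min(z_sup + 5.0, z1 - 1.0))
        curves["supreme"] = _bezier(q0, q0 + [s * 2.5, 2.5], q0 + [s * 4.0, 5.0], 25)

    hw = params.half_widths
    widths = {
        "inferior": hw["inferior"] * _y_profile(y, 34.0),
        "superior_main": hw["main"] * _y_profile(y, 30.0),
        "middle": hw["middle"] * _y_profile(y, 32.0),
        "superior": hw["superior"] * _y_profile(y, 38.0),
        "supreme": hw["supreme"] * _y_profile(y, 40.0),
    }
    out = {}
    for name, poly in curves.items():
        n = len(poly)
        taper = np.ones(n)
        if name in ("middle", "superior", "supreme"):
            taper = np.linspace(1.0, 0.55, n)  # meatuses thin toward their tips
        out[name] = (poly, widths[name] * taper)
    return out


# part grouping used for labels: the superior label covers the main channel
# above the branch point plus the superior (and supreme) meatuses
_PART_OF = {
    "inferior": "inferior",
    "middle": "middle",
    "superior_main": "superior",
    "superior": "superior",
    "supreme": "superior",
}


def _apply_congestion(params: SynthParams, side: str, name: str, hw: np.ndarray) -> np.ndarray:
    hw = hw.copy()
    n = len(hw)
    for c_side, c_part, (a0, a1) in params.congestion:
        if c_side == side and (c_part == name or c_part == _PART_OF[name]):
            i0, i1 = int(a0 * n), int(np.ceil(a1 * n))
            hw[i0:i1] = 0.0
    return hw


def _inverse_warp(warp: TPSTransform, extent, n_grid: int = 9) -> TPSTransform:
    """Approximate inverse of a smooth injective TPS by fitting the swapped
    dense-grid samples; accurate to well below a pixel for the small warps
    the generator draws."""
    (x0, x1), (z0, z1) = extent
    gx = np.linspace(x0, x1, n_grid)
    gz = np.linspace(z0, z1, n_grid)
    GX, GZ = np.meshgrid(gx, gz)
    grid = np.column_stack([GX.ravel(), GZ.ravel()])
    return tps_fit(warp(grid), grid, lam=0.0)


def make_section(
    params: SynthParams, y_position: float, warp: TPSTransform | None = None
) -> tuple[CrossSection, GroundTruth]:
    """Render one coronal cross-section with ground truth centerlines,
    branch points and part labels.

    With ``warp`` given, the section is the image-warp of the base shape
    (pixels pulled back through the warp's inverse, so passage widths
    transform with the deformation) and the ground-truth centerlines and
    branch points are the forward-warped base curves.
    """
    shape, spacing, ext = make_grid(params.extent, params.pixel_spacing)
    sec = CrossSection(np.zeros(shape, bool), spacing, y_position, ext)
    rows, cols = shape
    rc = np.stack(np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij"), -1).reshape(-1, 2)
    XZ = sec.pixel_to_xz(rc)  # (n_px, 2)
    # evaluate the base-frame geometry at pulled-back coordinates
    if warp is not None:
        XZ_base = _inverse_warp(warp, params.extent)(XZ)
    else:
        XZ_base = XZ

    centerlines, half_width, branch_points = {}, {}, {}
    score = {}  # (side, part) -> per-pixel max(hw - dist), in the base frame
    for side in ("right", "left"):
        curves = _side_curves(params, y_position, side)
        for name, (poly, hw) in curves.items():
            hw = _apply_congestion(params, side, name, hw)
            key = (side, name)
            centerlines[key] = warp(poly) if warp is not None else poly
            half_width[key] = hw
            part = _PART_OF[name]
            d2 = (
                (XZ_base[:, 0][:, None] - poly[None, :, 0]) ** 2
                + (XZ_base[:, 1][:, None] - poly[None, :, 1]) ** 2
            )
            margin = (hw[None, :] - np.sqrt(d2)).max(axis=1)
            if np.all(hw == 0):
                margin[:] = -np.inf
            pk = (side, part)
            score[pk] = np.maximum(score.get(pk, np.full(len(XZ), -np.inf)), margin)
        # ground-truth branch point: middle meatus root on the main channel
        branch_points[side] = centerlines[(side, "middle")][0].copy()

    label = np.zeros(len(XZ), dtype=np.int16)
    best = np.full(len(XZ), -np.inf)
    for (side, part), m in score.items():
        code = PART_CODES[part] + SIDE_OFFSET[side]
        take = (m >= 0) & (m > best)
        label[take] = code
        best = np.maximum(best, m)
    mask = label > 0
    if not mask.any():
        raise PipelineError("synthetic parameters produced an empty section")
    sec.mask = mask.reshape(shape)
    truth = GroundTruth(
        centerlines, half_width, branch_points, label.reshape(shape), warp
    )
    return sec, truth


# ---------------------------------------------------------------------------
# Population warps
# ---------------------------------------------------------------------------


def _warp_grid(params: SynthParams) -> np.ndarray:
    (x0, x1), (z0, z1) = params.extent
    gx = np.linspace(x0 + 5.0, x1 - 5.0, 4)
    gz = np.linspace(z0 + 4.0, z1 - 6.0, 4)
    GX, GZ = np.meshgrid(gx, gz)
    return np.column_stack([GX.ravel(), GZ.ravel()])


def _truncated_gaussian(rng: np.random.Generator, shape, sigma: float, bound: float):
    d = rng.normal(0.0, sigma, size=shape)
    while True:
        bad = np.abs(d) > bound
        if not bad.any():
            return d
        d[bad] = rng.normal(0.0, sigma, size=int(bad.sum()))


def _injective_scale(params: SynthParams, grid, disp) -> float:
    """Largest tested scale at which grid +/- scale*disp stays injective
    (positive sampled Jacobian determinant everywhere on the domain)."""
    (x0, x1), (z0, z1) = params.extent
    PX, PZ = np.meshgrid(np.linspace(x0, x1, 25), np.linspace(z0, z1, 25))
    probes = np.column_stack([PX.ravel(), PZ.ravel()])
    scale = 1.0
    for _ in range(12):
        ok = True
        for sgn in (1.0, -1.0):
            warp = tps_fit(grid, grid + sgn * scale * disp, lam=0.0)
            h = 0.25
            jx = (warp(probes + [h, 0]) - warp(probes - [h, 0])) / (2 * h)
            jz = (warp(probes + [0, h]) - warp(probes - [0, h])) / (2 * h)
            det = jx[:, 0] * jz[:, 1] - jx[:, 1] * jz[:, 0]
            ok = ok and det.min() > 0.05
        if ok:
            return scale
        scale *= 0.8
    return scale


def _sample_warp(params: SynthParams, rng: np.random.Generator) -> TPSTransform:
    """A zero-mean random TPS warp, injective on the section domain."""
    grid = _warp_grid(params)
    mag = params.warp_magnitude
    if mag == 0:
        return TPSTransform.identity(grid)
    disp = _truncated_gaussian(rng, grid.shape, mag / 2.0, mag)
    scale = _injective_scale(params, grid, disp)
    return tps_fit(grid, grid + scale * disp, lam=0.0)


def _population_warps(params: SynthParams, j: int) -> list[TPSTransform | None]:
    """Per-slice warps for all K scans, antithetically paired: scan 2p+1
    applies the negated control displacements of scan 2p (with a shared
    injectivity scale), so the sample-mean displacement field of an even
    cohort is exactly zero and the population mean shape is the base shape.
    An odd trailing scan keeps the identity warp."""
    if params.warp_magnitude == 0:
        return [None] * params.population_size
    grid = _warp_grid(params)
    warps: list[TPSTransform | None] = []
    for pair in range(params.population_size // 2):
        rng = np.random.default_rng(np.random.SeedSequence((params.seed, pair, j)))
        disp = _truncated_gaussian(rng, grid.shape, params.warp_magnitude / 2.0,
                                   params.warp_magnitude)
        scale = _injective_scale(params, grid, disp)
        warps.append(tps_fit(grid, grid + scale * disp, lam=0.0))
        warps.append(tps_fit(grid, grid - scale * disp, lam=0.0))
    if params.population_size % 2:
        warps.append(None)
    return warps


def make_population(params: SynthParams) -> Population:
    """K pseudo-scans: per-slice zero-mean TPS warps of one base anatomy,
    with landmarks at y=0 (AMS) and y=60 (choana). Reproducible from seed."""
    base_secs, base_truths = [], []
    for y in params.y_positions:
        sec, truth = make_section(params, y)
        base_secs.append(sec)
        base_truths.append(truth)
    landmarks = LandmarkPair(np.zeros(3), np.array([0.0, 60.0, 0.0]))
    per_slice_warps = [_population_warps(params, j) for j in range(len(params.y_positions))]
    scans = []
    for k in range(params.population_size):
        sections, truths = [], []
        for j, y in enumerate(params.y_positions):
            warp = per_slice_warps[j][k]
            p = params
            if params.width_jitter > 0:
                rng = np.random.default_rng(
                    np.random.SeedSequence((params.seed, 1_000_003 + k, j))
                )
                f = float(
                    np.clip(1.0 + rng.normal(0.0, params.width_jitter), 0.6, 1.4)
                )
                p = replace(
                    params, half_widths={k2: v * f for k2, v in params.half_widths.items()}
                )
            if warp is None:
                sec, truth = make_section(p, y)
            else:
                sec, truth = make_section(p, y, warp=warp)
            sections.append(sec)
            truths.append(truth)
        scans.append(Scan(sections, truths, landmarks))
    return Population(base_secs, base_truths, scans, params.y_positions)


def random_anatomy(seed: int) -> SynthParams:
    """A randomized anatomy draw: meatus count, septum deviation and passage
    widths vary over the ranges the generator is meant to emulate."""
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 17)))
    scale = {
        k: float(rng.uniform(0.85, 1.2)) for k in ("main", "inferior", "middle",
                                                   "superior", "supreme")
    }
    base = SynthParams()
    return replace(
        base,
        seed=int(seed),
        n_meatus=int(rng.choice([3, 4])),
        septum_deviation=float(rng.uniform(0.0, 4.0)),
        half_widths={k: v * scale[k] for k, v in base.half_widths.items()},
    )


def make_volume(params: SynthParams, y_spacing: float = 1.0) -> tuple[VolumeMask, LandmarkPair]:
    """Stack base sections into a 3-D volume (for slicing round-trip tests)."""
    ys = np.arange(params.y_positions[0], params.y_positions[-1] + 1e-9, y_spacing)
    secs = [make_section(params, float(y))[0] for y in ys]
    shape = secs[0].shape
    dx = dz = params.pixel_spacing
    # volume axes (x, y, z): x from columns, z from rows (flipped)
    vox = np.zeros((shape[1], len(ys), shape[0]), dtype=bool)
    for j, sec in enumerate(secs):
        vox[:, j, :] = sec.mask[::-1].T  # row 0 is z_max
    (x0, x1), (z0, z1) = secs[0].extent
    origin = np.array([x0 + dx / 2, ys[0], z0 + dz / 2])
    return VolumeMask(vox, (dx, y_spacing, dz), origin), LandmarkPair(
        np.zeros(3), np.array([0.0, 60.0, 0.0])
    )
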