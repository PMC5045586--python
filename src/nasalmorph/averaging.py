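"""Control-point averaging and median-geometry construction.

The core averaging algorithm: register the template to every scan's skeleton
(per slice), average the deformed control points across scans, warp every
scan's binary image to the average control coordinates, then take the
pixelwise mean, Gaussian-filter it and threshold at the median to obtain the
standardized geometry.  Optionally the median mask's skeleton becomes a new
reference template and the procedure repeats once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_alignment import ConfigError, CrossSection, PipelineError
from .registration import RPMConfig, rpm_register, tps_fit
from .skeleton import skeletonize_section, skeleton_to_pointset
from .template import RDPConfig, TemplateSlice, build_template

__all__ = [
    "AveragingConfig",
    "AverageGeometry",
    "average_control_points",
    "warp_to_average",
    "median_mask",
    "run_averaging_pipeline",
]

log = logging.getLogger("nasalmorph")


@dataclass
class AveragingConfig:
    """sigma: Gaussian filter width in mm applied to the stacked mean image
    (0.5 by default); threshold: median fraction, strict '>' comparison, so
    an exact split vote goes to background; iterate: rebuild the template
    from the median masks and rerun once."""

    sigma: float = 0.5
    threshold: float = 0.5
    iterate: bool = False
    min_scans_reliable: int = 3
    target_point_spacing: float = 0.86
    prune_length: float = 1.5

    def __post_init__(self):
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if not (0 < self.threshold < 1):
            raise ConfigError("threshold must be in (0, 1)")


@dataclass
class SliceAverage:
    y_position: float
    mean_controls: np.ndarray  # Ybar, (K_ctrl, 2) mm
    per_scan_controls: dict[int, np.ndarray]
    warped: dict[int, CrossSection]
    mean_image: np.ndarray | None
    median: CrossSection | None
    contributing: int = 0
    reliable: bool = True
    failures: dict[int, str] = field(default_factory=dict)


@dataclass
class AverageGeometry:
    slices: list[SliceAverage]

    @property
    def median_sections(self) -> list[CrossSection]:
        return [s.median for s in self.slices if s.median is not None]


def average_control_points(per_scan_controls: dict[int, np.ndarray]) -> np.ndarray:
    """Coordinate-wise arithmetic mean of the deformed control points over
    scans; permutation-invariant in the scan index."""
    if not per_scan_controls:
        raise PipelineError("no registered scans to average")
    stack = np.stack(list(per_scan_controls.values()))
    if stack.ndim != 3:
        raise PipelineError("control point arrays must share a shape")
    return stack.mean(axis=0)


def warp_to_average(
    section: CrossSection,
    own_controls: np.ndarray,
    mean_controls: np.ndarray,
    lam: float = 0.0,
    out_slice: "TemplateSlice | CrossSection | None" = None,
) -> CrossSection:
    """Deform a scan's binary image so its control points land on the mean.

    Backward mapping: the reverse-direction TPS (source = mean, target = own)
    is fitted and evaluated at every output pixel center; the input mask is
    sampled with nearest-neighbour lookup.  An exact TPS inverse has no
    closed form, and forward splatting leaves holes, hence this choice.
    Fold-over (negative Jacobian of the sampled reverse map) only logs a
    warning; the output is still produced.
    """
    own = np.asarray(own_controls, float).reshape(-1, 2)
    mean = np.asarray(mean_controls, float).reshape(-1, 2)
    if own.shape != mean.shape:
        raise PipelineError("control point sets must share indexing")
    if out_slice is None:
        out = CrossSection(
            np.zeros_like(section.mask), section.pixel_spacing, section.y_position, section.extent
        )
    elif isinstance(out_slice, CrossSection):
        out = CrossSection(
            np.zeros_like(out_slice.mask), out_slice.pixel_spacing, section.y_position,
            out_slice.extent,
        )
    else:
        out = out_slice.blank_section()
    reverse = tps_fit(mean, own, lam=lam)
    rows, cols = out.shape
    rc = np.stack(np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij"), -1).reshape(-1, 2)
    centers = out.pixel_to_xz(rc)
    src = reverse(centers)
    _check_foldover(reverse, centers[:: max(1, len(centers) // 256)])
    src_rc = np.round(section.xz_to_pixel(src)).astype(int)
    ok = (
        (src_rc[:, 0] >= 0) & (src_rc[:, 0] < section.shape[0])
        & (src_rc[:, 1] >= 0) & (src_rc[:, 1] < section.shape[1])
    )
    vals = np.zeros(len(rc), dtype=bool)
    vals[ok] = section.mask[src_rc[ok, 0], src_rc[ok, 1]]
    out.mask = vals.reshape(out.shape)
    return out


def _check_foldover(transform, probes: np.ndarray, h: float = 0.25) -> bool:
    jx = (transform(probes + [h, 0.0]) - transform(probes - [h, 0.0])) / (2 * h)
    jz = (transform(probes + [0.0, h]) - transform(probes - [0.0, h])) / (2 * h)
    det = jx[:, 0] * jz[:, 1] - jx[:, 1] * jz[:, 0]
    if det.min() <= 0:
        log.warning("TPS warp folds over (min sampled Jacobian %.3g)", det.min())
        return False
    return True


def median_mask(
    warped: list[CrossSection], config: AveragingConfig | None = None
) -> tuple[CrossSection, np.ndarray]:
    """Pixelwise mean of the warped binary stack, Gaussian filtered (sigma in
    mm) and thresholded (strict '>') into the median mask.

    With sigma = 0 and threshold 0.5 this is exactly the pixelwise majority
    vote.  Returns (median section, continuous mean image).
    """
    config = config or AveragingConfig()
    if not warped:
        raise PipelineError("empty warped stack")
    ref = warped[0]
    for w in warped[1:]:
        if w.shape != ref.shape or w.pixel_spacing != ref.pixel_spacing:
            raise PipelineError("warped sections must share one pixel grid")
    mean_img = np.mean([w.mask for w in warped], axis=0)
    filtered = mean_img
    if config.sigma > 0:
        sig_px = (config.sigma / ref.pixel_spacing[1], config.sigma / ref.pixel_spacing[0])
        filtered = ndimage.gaussian_filter(mean_img, sig_px)
    med = CrossSection(
        filtered > config.threshold, ref.pixel_spacing, ref.y_position, ref.extent
    )
    return med, mean_img


def _target_pointset(
    section: CrossSection, spacing: float, prune_length: float
) -> np.ndarray:
    graph = skeletonize_section(section, prune_length=prune_length)
    pts = skeleton_to_pointset(graph, spacing)
    if not pts:
        return np.zeros((0, 2))
    return np.vstack(list(pts.values()))


def run_averaging_pipeline(
    scans: list[list[CrossSection]],
    template: list[TemplateSlice],
    config: AveragingConfig | None = None,
    rpm: RPMConfig | None = None,
    rdp: RDPConfig | None = None,
) -> AverageGeometry:
    """Register every scan to the template, average control points, warp and
    take the median - slice by slice, in the standard order.

    ``scans[k][j]`` must be the aligned section of scan k at the template's
    j-th slice position.  Per-slice registration failures are logged and that
    scan excluded from the slice's average; a slice with fewer contributing
    scans than ``min_scans_reliable`` is marked unreliable.  With
    ``iterate=True`` the median masks are promoted to a new template and the
    whole procedure repeats once.
    """
    config = config or AveragingConfig()
    rpm = rpm or RPMConfig()
    if not scans:
        raise PipelineError("need at least one scan")
    n_slices = len(template)
    for k, scan in enumerate(scans):
        if len(scan) != n_slices:
            raise PipelineError(f"scan {k} has {len(scan)} sections, template {n_slices}")

    geometry = _run_once(scans, template, config, rpm)
    if config.iterate:
        med_secs = []
        for ts, sl in zip(template, geometry.slices):
            med_secs.append(sl.median if sl.median is not None else ts.blank_section())
        template2 = build_template(med_secs, rdp or RDPConfig(), prune_length=config.prune_length)
        geometry = _run_once(scans, template2, config, rpm)
    return geometry


def _run_once(scans, template, config: AveragingConfig, rpm: RPMConfig) -> AverageGeometry:
    out = []
    for j, ts in enumerate(template):
        if ts.empty or len(ts.control_coordinates()) < 3:
            out.append(
                SliceAverage(ts.y_position, np.zeros((0, 2)), {}, {}, None, None, 0, False)
            )
            continue
        controls = ts.control_coordinates()
        per_scan: dict[int, np.ndarray] = {}
        failures: dict[int, str] = {}
        for k, scan in enumerate(scans):
            try:
                tgt = _target_pointset(
                    scan[j], config.target_point_spacing, config.prune_length
                )
                if not len(tgt):
                    raise PipelineError("empty target skeleton")
                res = rpm_register(ts.reference_points, tgt, controls, rpm)
                per_scan[k] = res.control_points
            except PipelineError as exc:
                failures[k] = str(exc)
                log.warning("slice %g scan %d registration failed: %s", ts.y_position, k, exc)
        if not per_scan:
            out.append(
                SliceAverage(ts.y_position, np.zeros((0, 2)), {}, {}, None, None, 0, False, failures)
            )
            continue
        mean_controls = average_control_points(per_scan)
        warped = {
            k: warp_to_average(scans[k][j], per_scan[k], mean_controls, out_slice=ts)
            for k in per_scan
        }
        med, mean_img = median_mask(list(warped.values()), config)
        out.append(
            SliceAverage(
                ts.y_position, mean_controls, per_scan, warped, mean_img, med,
                contributing=len(per_scan),
                reliable=len(per_scan) >= config.min_scans_reliable,
                failures=failures,
            )
        )
    return AverageGeometry(out)
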