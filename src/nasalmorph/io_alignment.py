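"""Geometry I/O, landmark alignment, exterior-air removal and coronal slicing.

The working coordinate frame is the anatomical frame used throughout the
pipeline: x lateral (+x = subject's left), y posterior (anterior-posterior
axis), z superior.  The anterior maxillary spine (AMS) sits at the origin and
the choana on the +y axis, 60 mm away after uniform scaling.  All stored
positions are in millimetres.

Cross-section images live in the x-z plane: pixel ``(row, col)`` maps to
``(z, x)`` with row 0 at the superior edge and pixel centers at
``(i + 0.5) * spacing`` from the image border.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from PIL import Image

__all__ = [
    "PipelineError",
    "ConfigError",
    "DegenerateLandmarksError",
    "MissingMetadataError",
    "SchemaError",
    "LandmarkPair",
    "VolumeMask",
    "SurfaceMesh",
    "CrossSection",
    "AlignmentTransform",
    "PreprocessConfig",
    "compute_alignment",
    "apply_alignment",
    "remove_exterior_air",
    "slice_coronal",
    "read_landmarks",
    "write_landmarks",
    "read_transform",
    "write_transform",
    "read_nifti_mask",
    "write_nifti_mask",
    "read_mesh",
    "write_mesh",
    "read_section_stack",
    "write_section_stack",
]

DEFAULT_PIXEL_SPACING = 0.43  # mm, planar resolution of the source CT protocol
DEFAULT_AMS_CHOANA_DISTANCE = 60.0  # mm, normalised AMS-choana length


class PipelineError(Exception):
    """Base class for all errors raised by nasalmorph."""


class ConfigError(PipelineError):
    """Invalid configuration value."""


class DegenerateLandmarksError(PipelineError):
    """The AMS and choana landmarks coincide (zero-length axis)."""


class MissingMetadataError(PipelineError):
    """Required spacing / position metadata is absent from an input file."""


class SchemaError(PipelineError):
    """A JSON document does not match the expected schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandmarkPair:
    """The two bone landmarks that define the aligned frame.

    ams : tip of the anterior maxillary spine, mm.
    choana : point where the two choanae meet at the nasopharynx, mm.
    """

    ams: np.ndarray
    choana: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ams", np.asarray(self.ams, dtype=float))
        object.__setattr__(self, "choana", np.asarray(self.choana, dtype=float))
        if self.ams.shape != (3,) or self.choana.shape != (3,):
            raise SchemaError("landmarks must be 3-D points")
        if not (np.all(np.isfinite(self.ams)) and np.all(np.isfinite(self.choana))):
            raise SchemaError("landmarks must be finite")


@dataclass
class VolumeMask:
    """Binary voxel volume. ``voxels[ix, iy, iz]`` with mm axes (x, y, z).

    ``origin`` is the mm position of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise SchemaError("volume must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ConfigError("voxel spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[a] + np.arange(self.voxels.shape[a]) * self.spacing[a]
            for a in range(3)
        )


@dataclass
class SurfaceMesh:
    """Triangulated airway surface, vertices in mm."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise SchemaError("face indices out of range")

    def drop_degenerate_faces(self) -> "SurfaceMesh":
        if not len(self.faces):
            return self
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        area2 = np.linalg.norm(np.cross(b - a, c - a), axis=1)
        return SurfaceMesh(self.vertices, self.faces[area2 > 1e-12])

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass
class CrossSection:
    """A 2-D binary coronal mask at a stated y-position (mm posterior to AMS).

    ``extent`` is ``((x_min, x_max), (z_min, z_max))`` in mm; row 0 is the
    superior edge (z = z_max) and column 0 the x_min edge.
    """

    mask: np.ndarray
    pixel_spacing: tuple[float, float]  # (dx, dz) mm
    y_position: float
    extent: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise SchemaError("cross-section mask must be 2-D")
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        if min(self.pixel_spacing) <= 0:
            raise ConfigError("pixel spacing must be positive")
        (x0, x1), (z0, z1) = self.extent
        self.extent = ((float(x0), float(x1)), (float(z0), float(z1)))
        self.y_position = float(self.y_position)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def pixel_to_xz(self, rc: np.ndarray) -> np.ndarray:
        """Map (row, col) pixel indices (possibly fractional) to (x, z) mm."""
        rc = np.asarray(rc, dtype=float).reshape(-1, 2)
        dx, dz = self.pixel_spacing
        (x0, _), (_, z1) = self.extent
        x = x0 + (rc[:, 1] + 0.5) * dx
        z = z1 - (rc[:, 0] + 0.5) * dz
        return np.column_stack([x, z])

    def xz_to_pixel(self, xz: np.ndarray) -> np.ndarray:
        """Map (x, z) mm to fractional (row, col)."""
        xz = np.asarray(xz, dtype=float).reshape(-1, 2)
        dx, dz = self.pixel_spacing
        (x0, _), (_, z1) = self.extent
        col = (xz[:, 0] - x0) / dx - 0.5
        row = (z1 - xz[:, 1]) / dz - 0.5
        return np.column_stack([row, col])

    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.pixel_spacing[0] * self.pixel_spacing[1]


def make_grid(
    extent: tuple[tuple[float, float], tuple[float, float]],
    pixel_spacing: float | tuple[float, float] = DEFAULT_PIXEL_SPACING,
) -> tuple[tuple[int, int], tuple[float, float], tuple]:
    """Build a pixel grid covering ``extent``; returns (shape, spacing, extent).

    The extent's upper bounds are enlarged to an integer number of pixels.
    """
    if np.isscalar(pixel_spacing):
        dx = dz = float(pixel_spacing)
    else:
        dx, dz = map(float, pixel_spacing)
    (x0, x1), (z0, z1) = extent
    cols = max(1, int(np.ceil((x1 - x0) / dx - 1e-9)))
    rows = max(1, int(np.ceil((z1 - z0) / dz - 1e-9)))
    return (rows, cols), (dx, dz), ((x0, x0 + cols * dx), (z0, z0 + rows * dz))


def empty_section(
    y_position: float,
    extent: tuple[tuple[float, float], tuple[float, float]],
    pixel_spacing: float | tuple[float, float] = DEFAULT_PIXEL_SPACING,
) -> CrossSection:
    shape, spacing, ext = make_grid(extent, pixel_spacing)
    return CrossSection(np.zeros(shape, bool), spacing, y_position, ext)


@dataclass(frozen=True)
class AlignmentTransform:
    """Similarity transform ``p -> scale * R @ (p - ams)`` mapping the scan
    frame to the aligned anatomical frame."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        R = self.rotation
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ConfigError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ConfigError("rotation must be proper (det +1)")
        if self.scale <= 0:
            raise ConfigError("scale must be positive")

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return self.scale * (p @ self.rotation.T) + self.translation

    def invert_points(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return ((p - self.translation) / self.scale) @ self.rotation


@dataclass
class PreprocessConfig:
    """Preprocessing knobs: opening radius r, capture erosion radius r_eps,
    AMS-choana target distance, and analysis slice spacing (all mm)."""

    opening_radius: float = 10.0
    capture_erosion_radius: float = 2.0
    ams_choana_distance: float = DEFAULT_AMS_CHOANA_DISTANCE
    slice_spacing: float = 1.0

    def __post_init__(self):
        if self.opening_radius <= 0:
            raise ConfigError("opening_radius must be > 0")
        if self.capture_erosion_radius < 0:
            raise ConfigError("capture_erosion_radius must be >= 0")
        if self.ams_choana_distance <= 0 or self.slice_spacing <= 0:
            raise ConfigError("distances must be > 0")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def compute_alignment(
    landmarks: LandmarkPair,
    target_distance: float = DEFAULT_AMS_CHOANA_DISTANCE,
) -> AlignmentTransform:
    """Similarity transform placing the AMS at the origin, the choana at
    ``(0, target_distance, 0)``.

    The remaining degree of freedom (roll about the AMS-choana axis) is fixed
    canonically by mapping the scan's +z direction as close as possible to the
    aligned +z; the downstream 2-D matching is insensitive to this roll.
    """
    if target_distance <= 0:
        raise ConfigError("target_distance must be > 0")
    axis = landmarks.choana - landmarks.ams
    length = float(np.linalg.norm(axis))
    if length < 1e-12:
        raise DegenerateLandmarksError("AMS and choana coincide")
    y_axis = axis / length
    # Canonical roll: project +z off the AMS-choana axis; fall back to +x
    # when the axis is (anti)parallel to z.
    for ref in (np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])):
        z_axis = ref - np.dot(ref, y_axis) * y_axis
        n = np.linalg.norm(z_axis)
        if n > 1e-8:
            z_axis = z_axis / n
            break
    x_axis = np.cross(y_axis, z_axis)
    rotation = np.vstack([x_axis, y_axis, z_axis])
    scale = target_distance / length
    translation = -scale * rotation @ landmarks.ams
    return AlignmentTransform(rotation, translation, scale)


def apply_alignment(
    transform: AlignmentTransform,
    geometry: "VolumeMask | SurfaceMesh",
    out_spacing: float | None = None,
) -> "VolumeMask | SurfaceMesh":
    """Apply a similarity transform to a mesh or a binary volume.

    Volumes are resampled onto an axis-aligned grid (nearest-neighbour, since
    the data is binary); ``out_spacing`` defaults to the finest input spacing
    times the transform scale.
    """
    if isinstance(geometry, SurfaceMesh):
        return SurfaceMesh(transform.apply_points(geometry.vertices), geometry.faces)
    if not isinstance(geometry, VolumeMask):
        raise TypeError(f"cannot transform {type(geometry).__name__}")
    vol = geometry
    if not vol.voxels.any():
        return VolumeMask(vol.voxels.copy(), vol.spacing, vol.origin.copy())
    if out_spacing is None:
        out_spacing = min(vol.spacing) * transform.scale
    # Output bounding box from the transformed corners of the voxel grid.
    shp = np.array(vol.voxels.shape)
    corners = np.array(
        [[i * (shp[0] - 1), j * (shp[1] - 1), k * (shp[2] - 1)]
         for i in (0, 1) for j in (0, 1) for k in (0, 1)],
        dtype=float,
    )
    corners_mm = vol.origin + corners * np.array(vol.spacing)
    out_corners = transform.apply_points(corners_mm)
    lo = out_corners.min(axis=0) - out_spacing
    hi = out_corners.max(axis=0) + out_spacing
    n = np.maximum(1, np.ceil((hi - lo) / out_spacing).astype(int) + 1)
    axes = [lo[a] + np.arange(n[a]) * out_spacing for a in range(3)]
    PX, PY, PZ = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([PX.ravel(), PY.ravel(), PZ.ravel()])
    src = transform.invert_points(pts)
    idx = np.round((src - vol.origin) / np.array(vol.spacing)).astype(int)
    ok = np.all((idx >= 0) & (idx < shp), axis=1)
    out = np.zeros(len(pts), dtype=bool)
    out[ok] = vol.voxels[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return VolumeMask(out.reshape(tuple(n)), (out_spacing,) * 3, lo)


# ---------------------------------------------------------------------------
# Exterior-air removal
# ---------------------------------------------------------------------------


def _ball_erode(voxels: np.ndarray, radius: float, spacing) -> np.ndarray:
    """Exact erosion by the discretized ball {v : ||v * spacing|| <= radius}."""
    from scipy import ndimage

    if not voxels.any():
        return voxels.copy()
    d = ndimage.distance_transform_edt(voxels, sampling=spacing)
    return d > radius


def _ball_dilate(voxels: np.ndarray, radius: float, spacing) -> np.ndarray:
    from scipy import ndimage

    if voxels.all() or not voxels.any():
        return voxels.copy()
    d = ndimage.distance_transform_edt(~voxels, sampling=spacing)
    return voxels | (d <= radius)


def remove_exterior_air(volume: VolumeMask, config: PreprocessConfig) -> VolumeMask:
    """Remove the large exterior-air component in front of the face.

    A morphological opening with a spherical structuring element of radius r
    keeps only regions wide enough to fit the ball - i.e. the exterior volume;
    the interior passages (narrower than 2r) vanish.  The surviving (exterior)
    set, grown by the capture radius r_eps to pick up adjacent slivers the
    ball does not fit (e.g. the nose-lip channel), is subtracted from the
    input.  Anti-extensive and idempotent.
    """
    r = config.opening_radius
    if r <= 0:
        raise ConfigError("opening radius must be > 0")
    opened = _ball_dilate(_ball_erode(volume.voxels, r, volume.spacing), r, volume.spacing)
    if config.capture_erosion_radius > 0:
        captured = _ball_dilate(opened, config.capture_erosion_radius, volume.spacing)
    else:
        captured = opened
    return VolumeMask(volume.voxels & ~captured, volume.spacing, volume.origin.copy())


# ---------------------------------------------------------------------------
# Coronal slicing
# ---------------------------------------------------------------------------


def _chain_segments(segments: np.ndarray, gap_tol: float) -> list[np.ndarray]:
    """Chain unordered 2-D segments into closed contours.

    Endpoints closer than ``gap_tol`` are connected; a contour that cannot be
    closed raises a PipelineError.  Gap closing within tolerance emits a
    warning (open contours arise from slightly non-watertight meshes).
    """
    segs = [s for s in segments if np.linalg.norm(s[1] - s[0]) > 1e-12]
    used = np.zeros(len(segs), dtype=bool)
    contours = []
    snap = 1e-9
    for start in range(len(segs)):
        if used[start]:
            continue
        used[start] = True
        chain = [segs[start][0].copy(), segs[start][1].copy()]
        warned = False
        while True:
            end = chain[-1]
            if len(chain) > 2 and np.linalg.norm(end - chain[0]) <= snap:
                chain.pop()
                break
            best, best_d, best_flip = None, np.inf, False
            for j in range(len(segs)):
                if used[j]:
                    continue
                d0 = np.linalg.norm(segs[j][0] - end)
                d1 = np.linalg.norm(segs[j][1] - end)
                if d0 < best_d:
                    best, best_d, best_flip = j, d0, False
                if d1 < best_d:
                    best, best_d, best_flip = j, d1, True
            if best is not None and best_d <= gap_tol:
                if best_d > snap and not warned:
                    warnings.warn("closing open mesh contour gap during slicing")
                    warned = True
                used[best] = True
                p0, p1 = (segs[best][1], segs[best][0]) if best_flip else segs[best]
                chain.append(p1.copy())
            else:
                d_close = np.linalg.norm(end - chain[0])
                if d_close <= gap_tol:
                    if d_close > snap and not warned:
                        warnings.warn("closing open mesh contour gap during slicing")
                    break
                raise PipelineError(
                    f"open contour with gap {min(best_d, d_close):.3g} mm exceeds tolerance"
                )
        contours.append(np.array(chain))
    return contours


def _rasterize_contours(contours, section: CrossSection) -> np.ndarray:
    """Even-odd fill of closed contours: XOR of the filled polygons."""
    from skimage.draw import polygon2mask

    mask = np.zeros(section.shape, dtype=bool)
    for c in contours:
        if len(c) < 3:
            continue
        rc = section.xz_to_pixel(c)
        mask ^= polygon2mask(section.shape, rc)
    return mask


def slice_coronal(
    geometry: "VolumeMask | SurfaceMesh",
    positions,
    pixel_spacing: float | tuple[float, float] = DEFAULT_PIXEL_SPACING,
    extent=None,
) -> list[CrossSection]:
    """Extract coronal (constant-y) cross-sections from aligned geometry.

    For meshes each section is the even-odd rasterization of the plane-mesh
    intersection; for volumes the nearest voxel plane is resampled onto the
    requested pixel grid with nearest-neighbour lookup.
    """
    positions = [float(p) for p in np.atleast_1d(positions)]
    if isinstance(geometry, VolumeMask):
        return _slice_volume(geometry, positions, pixel_spacing, extent)
    if isinstance(geometry, SurfaceMesh):
        return _slice_mesh(geometry, positions, pixel_spacing, extent)
    raise TypeError(f"cannot slice {type(geometry).__name__}")


def _default_extent_from_bounds(lo, hi):
    return ((float(lo[0]), float(hi[0])), (float(lo[2]), float(hi[2])))


def _slice_volume(vol: VolumeMask, positions, pixel_spacing, extent):
    if extent is None:
        lo = vol.origin - 0.5 * np.array(vol.spacing)
        hi = vol.origin + np.array(vol.voxels.shape) * np.array(vol.spacing)
        extent = _default_extent_from_bounds(lo, hi)
    shape, spacing, ext = make_grid(extent, pixel_spacing)
    xs, ys, zs = vol.voxel_centers_mm()
    sections = []
    for y in positions:
        sec = CrossSection(np.zeros(shape, bool), spacing, y, ext)
        iy = int(round((y - vol.origin[1]) / vol.spacing[1]))
        if 0 <= iy < vol.voxels.shape[1]:
            plane = vol.voxels[:, iy, :]  # (x, z)
            centers = sec.pixel_to_xz(
                np.stack(np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij"), -1)
                .reshape(-1, 2)
            )
            ix = np.round((centers[:, 0] - vol.origin[0]) / vol.spacing[0]).astype(int)
            iz = np.round((centers[:, 1] - vol.origin[2]) / vol.spacing[2]).astype(int)
            ok = (ix >= 0) & (ix < plane.shape[0]) & (iz >= 0) & (iz < plane.shape[1])
            vals = np.zeros(len(centers), dtype=bool)
            vals[ok] = plane[ix[ok], iz[ok]]
            sec.mask = vals.reshape(shape)
        sections.append(sec)
    return sections


def _slice_mesh(mesh: SurfaceMesh, positions, pixel_spacing, extent):
    tm = mesh.drop_degenerate_faces().as_trimesh()
    if extent is None:
        lo, hi = tm.bounds
        pad = 2.0
        extent = ((lo[0] - pad, hi[0] + pad), (lo[2] - pad, hi[2] + pad))
    shape, spacing, ext = make_grid(extent, pixel_spacing)
    gap_tol = 2.0 * min(spacing)
    sections = []
    for y in positions:
        sec = CrossSection(np.zeros(shape, bool), spacing, y, ext)
        segs3 = trimesh.intersections.mesh_plane(
            tm, plane_normal=[0.0, 1.0, 0.0], plane_origin=[0.0, y, 0.0]
        )
        if len(segs3):
            segs2 = np.asarray(segs3)[:, :, [0, 2]]  # project to (x, z)
            contours = _chain_segments(segs2, gap_tol)
            sec.mask = _rasterize_contours(contours, sec)
        sections.append(sec)
    return sections


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def read_landmarks(path) -> LandmarkPair:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("ams", "choana"):
        if key not in doc:
            raise SchemaError(f"landmark file missing '{key}'")
    return LandmarkPair(np.array(doc["ams"], float), np.array(doc["choana"], float))


def write_landmarks(path, landmarks: LandmarkPair) -> None:
    with open(path, "w") as fh:
        json.dump({"ams": list(landmarks.ams), "choana": list(landmarks.choana)}, fh, indent=1)


def write_transform(path, transform: AlignmentTransform) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "rotation": transform.rotation.tolist(),
                "translation": transform.translation.tolist(),
                "scale": transform.scale,
            },
            fh,
            indent=1,
        )


def read_transform(path) -> AlignmentTransform:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("rotation", "translation", "scale"):
        if key not in doc:
            raise SchemaError(f"transform file missing '{key}'")
    return AlignmentTransform(
        np.array(doc["rotation"], float), np.array(doc["translation"], float), float(doc["scale"])
    )


def read_nifti_mask(path) -> VolumeMask:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    spacing = np.linalg.norm(rot, axis=0)
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise MissingMetadataError("NIfTI affine does not define a valid voxel spacing")
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-6 * spacing.max():
        raise PipelineError("only axis-aligned NIfTI volumes are supported")
    data = np.asanyarray(img.dataobj)
    return VolumeMask(data > 0, tuple(np.abs(np.diag(rot))), affine[:3, 3].copy())


def write_nifti_mask(path, volume: VolumeMask) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.voxels.astype(np.uint8), affine)
    nib.save(img, str(path))


def read_mesh(path) -> SurfaceMesh:
    tm = trimesh.load(str(path), force="mesh", process=False)
    return SurfaceMesh(np.array(tm.vertices), np.array(tm.faces)).drop_degenerate_faces()


def write_mesh(path, mesh: SurfaceMesh) -> None:
    mesh.as_trimesh().export(str(path))


def _stack_sidecar(sections: list[CrossSection]) -> dict:
    s0 = sections[0]
    return {
        "pixel_spacing_mm": list(s0.pixel_spacing),
        "y_positions_mm": [s.y_position for s in sections],
        "extent_mm": [list(s0.extent[0]), list(s0.extent[1])],
    }


def write_section_stack(directory, sections: list[CrossSection], fmt: str = "png") -> None:
    """Write a cross-section stack: one PNG per slice (or one multi-page TIFF)
    plus a ``stack.json`` sidecar holding spacing, positions and extent."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not sections:
        raise PipelineError("empty section stack")
    with open(directory / "stack.json", "w") as fh:
        json.dump(_stack_sidecar(sections), fh, indent=1)
    if fmt == "png":
        for i, sec in enumerate(sections):
            img = Image.fromarray((sec.mask.astype(np.uint8)) * 255)
            img.save(directory / f"section_{i:03d}.png")
    elif fmt == "tiff":
        import tifffile

        tifffile.imwrite(
            directory / "stack.tiff",
            np.stack([s.mask.astype(np.uint8) * 255 for s in sections]),
        )
    else:
        raise ConfigError(f"unknown stack format {fmt!r}")


def read_section_stack(directory) -> list[CrossSection]:
    directory = Path(directory)
    sidecar = directory / "stack.json"
    if not sidecar.exists():
        raise MissingMetadataError(
            f"{sidecar} not found: pixel spacing metadata is required, never defaulted"
        )
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("pixel_spacing_mm", "y_positions_mm"):
        if key not in meta:
            raise MissingMetadataError(f"stack sidecar missing '{key}'")
    spacing = tuple(meta["pixel_spacing_mm"])
    ys = meta["y_positions_mm"]
    tiff = directory / "stack.tiff"
    if tiff.exists():
        import tifffile

        frames = [np.asarray(f) > 0 for f in tifffile.imread(tiff)]
    else:
        paths = sorted(directory.glob("section_*.png"))
        frames = [np.array(Image.open(p)) > 0 for p in paths]
    if len(frames) != len(ys):
        raise SchemaError("stack sidecar y_positions_mm does not match image count")
    if "extent_mm" in meta:
        extent = tuple(tuple(b) for b in meta["extent_mm"])
    else:
        r, c = frames[0].shape
        extent = ((0.0, c * spacing[0]), (0.0, r * spacing[1]))
    return [CrossSection(f, spacing, y, extent) for f, y in zip(frames, ys)]
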