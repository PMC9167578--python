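"""Freehand 3D ultrasound reconstruction of free-tendon geometry.

A tracked sweep is an ordered sequence of B-mode frames, each carrying the
rigid pose of the ultrasound probe in a world (laboratory) frame and a
manually segmented cross-section contour in image pixel coordinates.  This
module turns such sweeps into the morphological quantities of interest:
free-tendon length (two-point landmark distance), per-slice cross-sectional
area (CSA), length-weighted mean CSA, and volume.

Conventions
-----------
* World frame: right-handed, millimetres.
* Image pixels: origin top-left, (row, column) order; the calibration
  transform carries the pixel spacing (mm/px) for each axis and the rigid
  image-plane -> probe-frame transform.
* Volume: linear interpolation of CSA between slice stations followed by
  trapezoidal integration, reported in ml (1 ml = 1000 mm^3).
* Slice station: projection of the slice centroid onto the chord joining
  the two anatomical landmarks (calcaneal notch, soleus muscle-tendon
  junction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from shapely.geometry import LineString

__all__ = [
    "Pose",
    "CalibrationTransform",
    "Frame",
    "TrackedSweep",
    "ContourSlice",
    "TendonGeometry",
    "pixel_to_world",
    "tendon_length",
    "contour_area",
    "reconstruct_volume",
    "mean_csa",
    "reconstruct_geometry",
]

#: max out-of-plane deviation (mm) tolerated for a "planar" contour;
#: matches the axial/lateral resolution of the imaging system.
PLANARITY_TOL_MM = 0.5

_ORTHONORMALITY_TOL = 1e-6


def _check_rotation(matrix: np.ndarray) -> np.ndarray:
    r = np.asarray(matrix, dtype=float)
    if r.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got shape {r.shape}")
    if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHONORMALITY_TOL):
        raise ValueError("rotation matrix is not orthonormal within 1e-6")
    return r


@dataclass(frozen=True)
class Pose:
    """Rigid transform probe frame -> world frame."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_quaternion(cls, quat_xyzw, translation) -> "Pose":
        """Build from a unit quaternion in scalar-last (x, y, z, w) order."""
        return cls(Rotation.from_quat(quat_xyzw).as_matrix(), translation)

    def as_quaternion(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_quat()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) or (3,) points from probe frame to world frame."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation


@dataclass(frozen=True)
class CalibrationTransform:
    """Image-plane -> probe-frame rigid transform plus pixel spacing.

    A pixel (row, col) maps to the metric image-plane point
    ``(col * col_spacing, row * row_spacing, 0)`` before the rigid part
    is applied.  The calibration is treated as a validated input; this
    package does not estimate it from phantom scans.
    """

    row_spacing_mm: float
    col_spacing_mm: float
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if self.row_spacing_mm <= 0 or self.col_spacing_mm <= 0:
            raise ValueError("pixel spacings must be positive")
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls, spacing_mm: float = 1.0) -> "CalibrationTransform":
        return cls(spacing_mm, spacing_mm)

    def pixels_to_probe(self, pixels_rc: np.ndarray) -> np.ndarray:
        px = np.atleast_2d(np.asarray(pixels_rc, dtype=float))
        plane = np.column_stack(
            [
                px[:, 1] * self.col_spacing_mm,
                px[:, 0] * self.row_spacing_mm,
                np.zeros(len(px)),
            ]
        )
        return plane @ self.rotation.T + self.translation


def pixel_to_world(pixel_rc, calibration: CalibrationTransform, pose: Pose) -> np.ndarray:
    """Map image pixel(s) into the world frame.

    Composition: pixel -> metric image plane -> probe frame (calibration)
    -> world frame (pose).  For fixed pixel spacing the map is rigid, i.e.
    distance-preserving up to the spacing scale.
    """
    single = np.asarray(pixel_rc).ndim == 1
    world = pose.apply(calibration.pixels_to_probe(pixel_rc))
    return world[0] if single else world


def tendon_length(landmark_a, landmark_b) -> float:
    """Free-tendon length: straight-line distance between the two landmarks
    (two-point method), in mm."""
    for name, lm in (("calcaneal notch", landmark_a), ("soleus-MTJ", landmark_b)):
        if lm is None:
            raise ValueError(f"missing landmark: {name}")
    a = np.asarray(landmark_a, dtype=float).reshape(3)
    b = np.asarray(landmark_b, dtype=float).reshape(3)
    return float(np.linalg.norm(b - a))


def _plane_basis(vertices: np.ndarray):
    """Best-fit plane of a vertex set: centroid, two in-plane axes, normal."""
    c = vertices.mean(axis=0)
    _, _, vt = np.linalg.svd(vertices - c, full_matrices=False)
    return c, vt[0], vt[1], vt[2]


def contour_area(polygon) -> float:
    """Area (mm^2) of a planar simple polygon given as ordered 3D vertices.

    Uses the vector shoelace formula about the centroid, so the result is
    independent of vertex orientation (absolute value).  Raises for
    self-intersecting or non-planar polygons.
    """
    v = np.asarray(polygon, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or len(v) < 3:
        raise ValueError("polygon must be an (N>=3, 3) vertex array")
    c, e1, e2, normal = _plane_basis(v)
    out_of_plane = np.abs((v - c) @ normal)
    if out_of_plane.max() > PLANARITY_TOL_MM:
        raise ValueError(
            f"contour deviates {out_of_plane.max():.3f} mm from its plane "
            f"(tolerance {PLANARITY_TOL_MM} mm)"
        )
    # simplicity check in the projected plane
    xy = np.column_stack([(v - c) @ e1, (v - c) @ e2])
    ring = LineString(np.vstack([xy, xy[:1]]))
    if not ring.is_simple:
        raise ValueError("self-intersecting contour")
    rel = v - c
    cross = np.cross(rel, np.roll(rel, -1, axis=0))
    return float(np.linalg.norm(cross.sum(axis=0)) / 2.0)


@dataclass(frozen=True)
class ContourSlice:
    """One segmented cross-section placed in the world frame."""

    vertices: np.ndarray  # (N, 3) world mm
    station_mm: float  # arclength coordinate along the tendon
    area_mm2: float = None  # type: ignore[assignment]

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if self.area_mm2 is None:
            object.__setattr__(self, "area_mm2", contour_area(v))
        if self.area_mm2 <= 0:
            raise ValueError("contour area must be positive")

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


def _station_profile(slices) -> tuple[np.ndarray, np.ndarray]:
    if len(slices) == 0:
        raise ValueError("no slices provided")
    stations = np.array([s.station_mm for s in slices], dtype=float)
    areas = np.array([s.area_mm2 for s in slices], dtype=float)
    if len(stations) > 1:
        d = np.diff(stations)
        if np.any(d <= 0):
            bad = stations[1:][d <= 0]
            raise ValueError(
                f"slice stations must be strictly increasing; offending stations: {bad}"
            )
    return stations, areas


def _integrated_area(stations, areas, step_mm) -> float:
    """Integral of the linearly interpolated CSA profile over the station range."""
    span = stations[-1] - stations[0]
    n = max(int(np.ceil(span / step_mm)), 1) + 1
    grid = np.linspace(stations[0], stations[-1], n)
    return float(np.trapezoid(np.interp(grid, stations, areas), grid))


def reconstruct_volume(slices, step_mm: float = 0.1) -> float:
    """Tendon volume in ml from ordered contour slices.

    CSA is linearly interpolated between consecutive stations at ``step_mm``
    resolution and integrated with the trapezoidal rule — exact for linear
    area profiles.
    """
    stations, areas = _station_profile(slices)
    if len(stations) < 2:
        raise ValueError("volume needs at least 2 slices")
    return _integrated_area(stations, areas, step_mm) / 1000.0


def mean_csa(slices, step_mm: float = 0.1) -> float:
    """Length-weighted mean CSA (mm^2): integral of the interpolated area
    profile divided by the station span.  Satisfies the exact identity
    ``mean_csa * span / 1000 == reconstruct_volume`` on the same slices."""
    stations, areas = _station_profile(slices)
    if len(stations) == 1:
        return float(areas[0])
    span = stations[-1] - stations[0]
    return _integrated_area(stations, areas, step_mm) / span


@dataclass(frozen=True)
class Frame:
    """One tracked ultrasound frame: probe pose + segmented contour."""

    pose: Pose
    contour_px: np.ndarray  # (N, 2) pixel (row, col), float
    landmark: str | None = None  # "calcaneal_notch" | "soleus_mtj" | None

    def __post_init__(self):
        object.__setattr__(
            self, "contour_px", np.asarray(self.contour_px, dtype=float)
        )


@dataclass
class TrackedSweep:
    """An ordered freehand sweep with its (validated) spatial calibration."""

    frames: list
    calibration: CalibrationTransform
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.frames)

    # -- JSON interchange ---------------------------------------------------
    def to_json(self, path=None) -> str | None:
        payload = {
            "coordinate_frame": "right-handed world frame, mm; "
            "pixels row-col from top-left; quaternion scalar-last (x,y,z,w)",
            "calibration": {
                "row_spacing_mm": self.calibration.row_spacing_mm,
                "col_spacing_mm": self.calibration.col_spacing_mm,
                "quaternion_xyzw": Rotation.from_matrix(
                    self.calibration.rotation
                ).as_quat().tolist(),
                "translation_mm": self.calibration.translation.tolist(),
            },
            "meta": self.meta,
            "frames": [
                {
                    "quaternion_xyzw": f.pose.as_quaternion().tolist(),
                    "translation_mm": f.pose.translation.tolist(),
                    "contour_px": f.contour_px.tolist(),
                    "landmark": f.landmark,
                }
                for f in self.frames
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
            return None
        return text

    @classmethod
    def from_json(cls, source) -> "TrackedSweep":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        cal = payload["calibration"]
        calibration = CalibrationTransform(
            cal["row_spacing_mm"],
            cal["col_spacing_mm"],
            Rotation.from_quat(cal["quaternion_xyzw"]).as_matrix(),
            np.asarray(cal["translation_mm"]),
        )
        frames = [
            Frame(
                Pose.from_quaternion(f["quaternion_xyzw"], f["translation_mm"]),
                np.asarray(f["contour_px"]),
                f.get("landmark"),
            )
            for f in payload["frames"]
        ]
        return cls(frames, calibration, payload.get("meta", {}))


@dataclass(frozen=True)
class TendonGeometry:
    """Per-state morphological summary of the free tendon."""

    length_mm: float
    slices: tuple
    mean_csa_mm2: float
    volume_ml: float

    def to_json(self, path=None):
        payload = {
            "length_mm": self.length_mm,
            "mean_csa_mm2": self.mean_csa_mm2,
            "volume_ml": self.volume_ml,
            "slices": [
                {"station_mm": s.station_mm, "area_mm2": s.area_mm2}
                for s in self.slices
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
            return None
        return text


def _world_contours(sweep: TrackedSweep):
    for f in sweep.frames:
        yield f, pixel_to_world(f.contour_px, sweep.calibration, f.pose)


def reconstruct_geometry(
    sweep: TrackedSweep,
    step_mm: float = 0.1,
    slice_interval_mm: float | None = None,
) -> TendonGeometry:
    """Full reconstruction of a tracked sweep into :class:`TendonGeometry`.

    Landmarks are taken from the flagged frames (their contour centroid in
    world coordinates).  Slice stations are the projections of contour
    centroids onto the landmark chord.  When ``slice_interval_mm`` is given,
    frames are subsampled so consecutive retained slices are at least that
    far apart — emulating manual contouring at sparse intervals; otherwise
    every frame contributes a slice.
    """
    landmarks = {}
    world_frames = []
    for frame, world in _world_contours(sweep):
        world_frames.append((frame, world))
        if frame.landmark:
            landmarks[frame.landmark] = world.mean(axis=0)
    a = landmarks.get("calcaneal_notch")
    b = landmarks.get("soleus_mtj")
    length = tendon_length(a, b)
    if length <= 0:
        raise ValueError("landmarks coincide; cannot orient the tendon axis")
    axis = (b - a) / length

    slices = []
    last_station = None
    for i, (frame, world) in enumerate(world_frames):
        station = float((world.mean(axis=0) - a) @ axis)
        is_end = i == 0 or i == len(world_frames) - 1
        if (
            slice_interval_mm is not None
            and not is_end
            and last_station is not None
            and station - last_station < slice_interval_mm
        ):
            continue
        slices.append(ContourSlice(world, station))
        last_station = station
    slices.sort(key=lambda s: s.station_mm)
    volume = reconstruct_volume(slices, step_mm=step_mm)
    csa = mean_csa(slices, step_mm=step_mm)
    return TendonGeometry(length, tuple(slices), csa, volume)
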