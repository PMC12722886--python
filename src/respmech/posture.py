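"""Centre of pressure, whole-body centre of mass, and joint-angle kinematics.

Axis convention (lab frame): X anteroposterior, Y mediolateral, Z vertical
(positive up).  COP and COM are in metres, joint angles in degrees; the
internal trigonometry is in radians.

The COM uses a proportional segment model: each body segment contributes
``mass_fraction * (P_prox + com_fraction * (P_dist - P_prox))``, with mass
and COM-location fractions from standard adult anthropometric tables (the
default 14-segment model ships as editable YAML).

Joint angles are Cardan decompositions of the distal segment's orientation
relative to the proximal one, in the fixed flexion -> abduction -> rotation
sequence (the dominant gait-analysis convention): first angle sagittal
plane, second frontal, third transverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .mocap_io import ForcePlateRecord, MarkerTrajectorySet

__all__ = [
    "CopSeries",
    "ComTrajectory",
    "JointAngleSeries",
    "SegmentModel",
    "Segment",
    "load_segment_model",
    "default_segment_model",
    "cop_from_forceplate",
    "cop_displacement",
    "whole_body_com",
    "segment_frames",
    "cardan_angles",
    "joint_rom",
]

MM_PER_M = 1000.0

PLANES = ("sagittal", "frontal", "transverse")


@dataclass
class CopSeries:
    """Centre-of-pressure trajectory on one force plate, in metres.

    Samples where the vertical load was below the contact threshold are NaN;
    ``valid_mask`` marks the loaded frames.
    """

    time: np.ndarray
    cop_x: np.ndarray  # anteroposterior, m
    cop_y: np.ndarray  # mediolateral, m
    valid_mask: np.ndarray
    plate_id: str = "FP1"

    @property
    def empty(self) -> bool:
        return not bool(self.valid_mask.any())


@dataclass
class ComTrajectory:
    """Whole-body centre-of-mass trajectory in metres."""

    time: np.ndarray
    com: np.ndarray  # (n, 3)

    @property
    def com_x(self) -> np.ndarray:
        return self.com[:, 0]

    @property
    def com_y(self) -> np.ndarray:
        return self.com[:, 1]

    @property
    def com_z(self) -> np.ndarray:
        return self.com[:, 2]

    @property
    def rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


@dataclass
class JointAngleSeries:
    """Tri-planar joint angles (degrees), unwrapped over time."""

    joint: str
    side: str
    time: np.ndarray
    angles: np.ndarray  # (n, 3): sagittal, frontal, transverse
    gimbal_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gimbal_mask is None:
            self.gimbal_mask = np.zeros(self.angles.shape[0], dtype=bool)

    def plane(self, name: str) -> np.ndarray:
        return self.angles[:, PLANES.index(name)]


@dataclass(frozen=True)
class Segment:
    name: str
    proximal: str  # marker label
    distal: str
    mass_fraction: float
    com_fraction: float  # along proximal -> distal axis


@dataclass(frozen=True)
class SegmentModel:
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        total = sum(s.mass_fraction for s in self.segments)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"segment mass fractions sum to {total}, not 1")

    @property
    def marker_labels(self) -> list[str]:
        out: list[str] = []
        for s in self.segments:
            for lab in (s.proximal, s.distal):
                if lab not in out:
                    out.append(lab)
        return out


def load_segment_model(source: str | Path | dict) -> SegmentModel:
    """Load a segment model from YAML (path or already-parsed mapping).

    Expected layout::

        segments:
          thigh_R: {proximal: RHIP, distal: RKNE, mass_fraction: 0.1416,
                    com_fraction: 0.4095}
    """
    if not isinstance(source, dict):
        source = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    segs = tuple(
        Segment(
            name=name,
            proximal=spec["proximal"],
            distal=spec["distal"],
            mass_fraction=float(spec["mass_fraction"]),
            com_fraction=float(spec["com_fraction"]),
        )
        for name, spec in source["segments"].items()
    )
    return SegmentModel(segs)


def default_segment_model() -> SegmentModel:
    """The 14-segment model shipped with the package."""
    text = resources.files("respmech").joinpath("config/segments.yaml").read_text("utf-8")
    return load_segment_model(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# centre of pressure
# ---------------------------------------------------------------------------


def cop_from_forceplate(plate: ForcePlateRecord, fz_threshold: float = 20.0) -> CopSeries:
    """COP from plate forces and moments about the plate origin.

    With the vertical force positive upward, the loaded-plate moment balance
    gives ``cop_x = -My / Fz`` and ``cop_y = Mx / Fz`` (plus the plate-origin
    offset in the lab frame).  Frames with ``Fz < fz_threshold`` (default
    20 N) are masked — the ratio is meaningless on an unloaded plate.
    """
    if not fz_threshold > 0:
        raise ValueError("fz_threshold must be > 0")
    fz = plate.forces[:, 2]
    loaded = fz >= fz_threshold
    ox, oy, _ = plate.origin_offset
    with np.errstate(divide="ignore", invalid="ignore"):
        cop_x = np.where(loaded, -plate.moments[:, 1] / fz + ox, np.nan)
        cop_y = np.where(loaded, plate.moments[:, 0] / fz + oy, np.nan)
    return CopSeries(
        time=plate.time, cop_x=cop_x, cop_y=cop_y, valid_mask=loaded,
        plate_id=plate.plate_id,
    )


def cop_displacement(cop: CopSeries, window: tuple[float, float]) -> tuple[float, float]:
    """COP range (max - min, metres) in X and Y within a movement cycle."""
    start, end = window
    if start >= cop.time[-1] or end <= cop.time[0]:
        raise ValueError(f"window ({start}, {end}) s lies outside the COP series")
    sel = (cop.time >= start) & (cop.time <= end) & cop.valid_mask
    if sel.sum() < 2:
        raise ValueError("fewer than 2 loaded COP samples in the window")
    x, y = cop.cop_x[sel], cop.cop_y[sel]
    return float(x.max() - x.min()), float(y.max() - y.min())


# ---------------------------------------------------------------------------
# centre of mass
# ---------------------------------------------------------------------------


def whole_body_com(markers: MarkerTrajectorySet, model: SegmentModel) -> ComTrajectory:
    """Mass-weighted mean of segment COMs, in metres."""
    com = np.zeros((markers.n_frames, 3))
    for seg in model.segments:
        try:
            prox = markers.get(seg.proximal)
            dist = markers.get(seg.distal)
        except KeyError as exc:
            raise KeyError(f"segment {seg.name!r}: {exc.args[0]}") from None
        com += seg.mass_fraction * (prox + seg.com_fraction * (dist - prox))
    return ComTrajectory(time=markers.time, com=com / MM_PER_M)


# ---------------------------------------------------------------------------
# joint angles
# ---------------------------------------------------------------------------


def segment_frames(
    markers: MarkerTrajectorySet, origin: str, along: str, lateral: str
) -> np.ndarray:
    """Per-frame orthonormal segment frames from a three-marker triad.

    Local axes: Z longitudinal (``along`` -> ``origin``, i.e. pointing
    proximally), X mediolateral (the ``lateral`` marker's direction made
    orthogonal to Z), Y = Z x X (anteroposterior).  Returns rotation
    matrices of shape ``(n_frames, 3, 3)`` whose columns are X, Y, Z in lab
    coordinates.
    """
    o = markers.get(origin)
    a = markers.get(along)
    l = markers.get(lateral)
    z = o - a
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    t = l - a
    x = t - np.sum(t * z, axis=1, keepdims=True) * z
    x = x / np.linalg.norm(x, axis=1, keepdims=True)
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=2)


def cardan_angles(
    proximal: np.ndarray,
    distal: np.ndarray,
    time: np.ndarray,
    joint: str = "",
    side: str = "",
    gimbal_limit_deg: float = 85.0,
) -> JointAngleSeries:
    """Cardan angles of the distal segment relative to the proximal one.

    ``proximal`` and ``distal`` are stacks of orthonormal rotation matrices
    ``(n, 3, 3)``.  The relative rotation ``R_prox^T R_dist`` is decomposed
    in the intrinsic X-Y-Z sequence (flexion about the mediolateral X axis,
    abduction about the anteroposterior Y axis, axial rotation about the
    longitudinal Z axis), unwrapped over time and returned in degrees.
    Frames within ``gimbal_limit_deg`` of the second-axis singularity are
    flagged, not raised.
    """
    for name, mats in (("proximal", proximal), ("distal", distal)):
        det = np.linalg.det(mats)
        if np.any(np.abs(det - 1.0) > 1e-6):
            raise ValueError(f"{name} frames are not orthonormal (|det-1| > 1e-6)")
    rel = np.einsum("nji,njk->nik", proximal, distal)  # R_prox^T @ R_dist
    ang = Rotation.from_matrix(rel).as_euler("XYZ")  # radians
    ang = np.unwrap(ang, axis=0)
    gimbal = np.abs(np.degrees(ang[:, 1])) > gimbal_limit_deg
    return JointAngleSeries(
        joint=joint, side=side, time=np.asarray(time, dtype=float),
        angles=np.degrees(ang), gimbal_mask=gimbal,
    )


def joint_rom(angles: JointAngleSeries, window: tuple[float, float]) -> dict[str, float]:
    """Per-plane range of motion (max - min, degrees) within a window."""
    start, end = window
    sel = (angles.time >= start) & (angles.time <= end)
    if sel.sum() < 2:
        raise ValueError(f"window ({start}, {end}) s covers < 2 angle samples")
    a = angles.angles[sel]
    return {p: float(a[:, i].max() - a[:, i].min()) for i, p in enumerate(PLANES)}
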