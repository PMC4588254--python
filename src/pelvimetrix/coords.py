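"""Pelvis-specific coordinate frame, rigid transforms and radiographic projections.

The pelvic ring gets its own Cartesian frame, anchored at the centre of the
superior S1 endplate (``S``):

* ``+X`` — transverse axis, toward the patient's left;
* ``+Y`` — perpendicular to the inlet plane (cephalad along the pelvic ring);
* ``+Z`` — perpendicular to the outlet plane (anterior).

The standard inlet and outlet radiographs are modelled as orthographic
(parallel-beam) projections onto the X/Z and X/Y coordinate planes
respectively.  The AP radiograph does not coincide with a coordinate plane
because pelvic obliquity varies between patients (roughly 40-60 degrees); it
is modelled as the inlet beam tilted about X by a configurable angle.

Named hemipelvis rotations follow the frame's right-hand rule: varus/valgus
turn about Z (outlet plane), internal/external rotation about Y (inlet
plane), flexion/extension about X (sagittal plane).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class Point3(NamedTuple):
    """A 3D point in the pelvis frame (mm)."""

    x: float
    y: float
    z: float


class Point2(NamedTuple):
    """A 2D image point. ``unit`` is either ``"px"`` or ``"mm"``."""

    u: float
    v: float
    unit: str = "mm"


def _as_points(points: Iterable) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[-1] != 3:
        raise ValidationError(f"expected 3D points, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite coordinates in point set")
    return arr


@dataclass(frozen=True)
class View:
    """An orthographic radiographic view.

    ``projection_axis`` is the beam direction (depth, discarded);
    ``u_basis``/``v_basis`` span the image plane.  All three must form an
    orthonormal triad.
    """

    name: str
    projection_axis: tuple[float, float, float]
    u_basis: tuple[float, float, float]
    v_basis: tuple[float, float, float]

    def __post_init__(self) -> None:
        basis = np.array([self.projection_axis, self.u_basis, self.v_basis], float)
        gram = basis @ basis.T
        if not np.allclose(gram, np.eye(3), atol=1e-9):
            raise ValidationError(f"view {self.name!r}: basis is not orthonormal")

    @property
    def image_basis(self) -> np.ndarray:
        return np.array([self.u_basis, self.v_basis], float)


#: Inlet view: beam along +Y, image (u, v) = (x, z); v increases anteriorly.
INLET_VIEW = View("inlet", (0.0, 1.0, 0.0), (1.0, 0.0, 0.0), (0.0, 0.0, 1.0))

#: Outlet view: beam along +Z, image (u, v) = (x, y); v increases superiorly.
OUTLET_VIEW = View("outlet", (0.0, 0.0, 1.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0))


def make_ap_view(tilt_deg: float = 45.0) -> View:
    """Build the AP view as the inlet beam tilted by ``tilt_deg`` about X.

    ``tilt_deg`` is the pelvic obliquity: the angle between the AP beam and
    the inlet (Y) axis, strictly between 0 and 90 degrees.  The image
    vertical is chosen so that superior maps to +v.
    """
    if not (0.0 < tilt_deg < 90.0):
        raise ValidationError(f"AP tilt must lie in (0, 90) degrees, got {tilt_deg}")
    t = np.deg2rad(tilt_deg)
    axis = (0.0, float(np.cos(t)), float(np.sin(t)))
    v_basis = (0.0, float(np.sin(t)), float(-np.cos(t)))
    return View("ap", axis, (1.0, 0.0, 0.0), v_basis)


def standard_views(ap_tilt_deg: float = 45.0) -> dict[str, View]:
    """The three standardized radiographic views keyed by name."""
    return {"inlet": INLET_VIEW, "outlet": OUTLET_VIEW, "ap": make_ap_view(ap_tilt_deg)}


@dataclass(frozen=True)
class RigidTransform:
    """Rigid-body displacement: rotation about a pivot, then a translation.

    Rotations are intrinsic X->Y->Z Euler angles in degrees, applied about
    ``pivot``; ``translation`` is in mm.  Distances between points are
    preserved exactly (up to floating point).
    """

    rot_x_deg: float = 0.0
    rot_y_deg: float = 0.0
    rot_z_deg: float = 0.0
    pivot: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vals = [self.rot_x_deg, self.rot_y_deg, self.rot_z_deg, *self.pivot, *self.translation]
        if not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite rigid-transform parameters")

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler(
            "XYZ", [self.rot_x_deg, self.rot_y_deg, self.rot_z_deg], degrees=True
        )


def apply_rigid(points: Iterable, t: RigidTransform) -> np.ndarray:
    """Apply a rigid transform to an (N, 3) point set; returns (N, 3) mm."""
    arr = _as_points(points)
    pivot = np.asarray(t.pivot, float)
    shift = np.asarray(t.translation, float)
    return t.rotation.apply(arr - pivot) + pivot + shift


def project(points: Iterable, view: View) -> np.ndarray:
    """Orthographically project (N, 3) mm points into a view; returns (N, 2) mm.

    (u, v) are coordinates in the view's image basis; depth along the
    projection axis is discarded.
    """
    arr = _as_points(points)
    return arr @ view.image_basis.T


def mm_per_pixel(fh_true_mm: float, fh_pixels: float) -> float:
    """Fiducial calibration from the intact femoral head diameter.

    The head's true diameter (from the 3D model / calibration record) over
    its measured pixel diameter in the same image gives the image scale.
    """
    if not (fh_true_mm > 0 and fh_pixels > 0):
        raise ValidationError(
            f"femoral head diameters must be positive, got {fh_true_mm} mm / {fh_pixels} px"
        )
    return float(fh_true_mm) / float(fh_pixels)
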