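"""Displacement measurement of an injured hemipelvis from landmark sheets.

The measurement system reads per-view 2D coordinates of a small set of bony
landmarks, calibrates pixels to millimetres via the intact femoral head
diameter, and evaluates difference-of-distance formulas that quantify the
three translational displacements and classify the three rotational
displacements of the injured hemipelvis against the intact side.

Landmark scheme (primed symbols denote the injured side):

* AP view — ASIS (A, A'), ischial tuberosity (B, B');
* outlet view — superior iliac wing point (C, C'), ischial tuberosity
  (D, D'), ASIS (E, E'), sacral endplate centre (S);
* inlet view — ASIS (G, G'), anterior SI joint, iliac side (H, H'), S.

Formulas (image coordinates in mm; v vertical within the view, u horizontal):

* vertical (outlet):    |v(C') - v(S)| - |v(C) - v(S)|   (>0 cephalad)
* antero-posterior (inlet): |v(H') - v(S)| - |v(H) - v(S)|  (>0 anterior)
* transverse (inlet):   |u(H') - u(S)| - |u(H) - u(S)|   (>0 lateral)
* sagittal rotation (AP):   |v(A) - v(B)| - |v(A') - v(B')|
* inlet-plane rotation:     |u(G) - u(H)| - |u(G') - u(H')|
* outlet-plane rotation:    |u(E) - u(D)| - |u(E') - u(D')|

A rotational indicator within ``[-threshold, +threshold]`` (default 2 mm,
the anatomic-reduction band of the Majeed convention) is classified as
neutral; beyond the band the sign names the rotation direction.  Because
the published direction names for the sagittal and outlet planes are stated
inconsistently between the canonical table and the accompanying prose, a
``label_convention`` switch selects which naming to report; the geometry
and numbers are identical under both.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .coords import Point2, ValidationError, mm_per_pixel

VIEWS = ("ap", "outlet", "inlet")
SIDES = ("intact", "injured", "midline")

#: Landmark vocabulary accepted in sheets / CSV files.
LANDMARKS = (
    "ASIS",
    "ischial_tuberosity",
    "iliac_wing_superior",
    "anterior_SI_joint",
    "sacral_endplate_centre",
    "femoral_head_d1",
    "femoral_head_d2",
)

#: Measurement landmarks required per view (femoral-head marks are optional
#: when the calibration record carries a pixel diameter directly).
VIEW_LANDMARKS: dict[str, tuple[tuple[str, str], ...]] = {
    "ap": (("ASIS", "intact"), ("ASIS", "injured"),
           ("ischial_tuberosity", "intact"), ("ischial_tuberosity", "injured")),
    "outlet": (("iliac_wing_superior", "intact"), ("iliac_wing_superior", "injured"),
               ("ischial_tuberosity", "intact"), ("ischial_tuberosity", "injured"),
               ("ASIS", "intact"), ("ASIS", "injured"),
               ("sacral_endplate_centre", "midline")),
    "inlet": (("ASIS", "intact"), ("ASIS", "injured"),
              ("anterior_SI_joint", "intact"), ("anterior_SI_joint", "injured"),
              ("sacral_endplate_centre", "midline")),
}

ROTATION_CLASSES = {
    "table2": {
        "sagittal": ("flexion", "neutral", "extension"),
        "inlet": ("external", "neutral", "internal"),
        "outlet": ("valgus", "neutral", "varus"),
    },
    # Naming used in the descriptive prose: flexion/extension and
    # varus/valgus swapped relative to the canonical table.
    "text": {
        "sagittal": ("extension", "neutral", "flexion"),
        "inlet": ("external", "neutral", "internal"),
        "outlet": ("varus", "neutral", "valgus"),
    },
}

TRANSLATION_DIRECTIONS = {
    "vertical": ("caudad", "none", "cephalad"),
    "ap": ("posterior", "none", "anterior"),
    "transverse": ("medial", "none", "lateral"),
}


class MissingLandmarkError(ValidationError):
    """A formula's landmark is absent from the sheet."""

    def __init__(self, missing: list[tuple[str, str, str]]):
        self.missing = missing
        desc = ", ".join(f"{lm}/{side} in {view} view" for view, lm, side in missing)
        super().__init__(f"missing landmark(s): {desc}")


@dataclass(frozen=True)
class Calibration:
    """Per-view fiducial record: true femoral head diameter and its pixel size."""

    fh_true_mm: float
    fh_px: float

    @property
    def scale(self) -> float:
        return mm_per_pixel(self.fh_true_mm, self.fh_px)


@dataclass
class LandmarkSheet:
    """Per-subject 2D landmark coordinates across the three standardized views.

    ``points`` maps view -> (landmark, side) -> Point2.  Coordinates are
    stored in the unit given by each point's flag; ``calibrated()`` returns
    a copy with every view converted to mm using its femoral-head scale.
    """

    subject_id: str
    injured_side: str
    points: dict[str, dict[tuple[str, str], Point2]]
    calibration: dict[str, Calibration] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # "unspecified" is allowed for hand-authored sheets: the formulas
        # only distinguish intact vs injured, not left vs right.
        if self.injured_side not in ("left", "right", "unspecified"):
            raise ValidationError(f"injured_side must be left/right, got {self.injured_side!r}")
        for view in self.points:
            if view not in VIEWS:
                raise ValidationError(f"unknown view {view!r}; expected one of {VIEWS}")

    def get(self, view: str, landmark: str, side: str) -> Point2:
        try:
            return self.points[view][(landmark, side)]
        except KeyError:
            raise MissingLandmarkError([(view, landmark, side)]) from None

    def has(self, view: str, landmark: str, side: str) -> bool:
        return (landmark, side) in self.points.get(view, {})

    def iter_points(self) -> Iterator[tuple[str, str, str, Point2]]:
        for view, pts in self.points.items():
            for (lm, side), p in pts.items():
                yield view, lm, side, p

    def view_scale(self, view: str) -> float:
        """mm-per-pixel for a view, from the calibration record or the
        femoral-head diameter marks present in the sheet itself."""
        cal = self.calibration.get(view)
        if cal is not None and cal.fh_px > 0:
            return cal.scale
        if cal is not None and self.has(view, "femoral_head_d1", "intact") \
                and self.has(view, "femoral_head_d2", "intact"):
            p1 = self.get(view, "femoral_head_d1", "intact")
            p2 = self.get(view, "femoral_head_d2", "intact")
            fh_px = float(np.hypot(p1.u - p2.u, p1.v - p2.v))
            return mm_per_pixel(cal.fh_true_mm, fh_px)
        raise ValidationError(
            f"subject {self.subject_id!r}: no usable calibration for the {view} view"
        )

    def calibrated(self) -> "LandmarkSheet":
        """Return a copy with all coordinates in mm."""
        new_points: dict[str, dict[tuple[str, str], Point2]] = {}
        for view, pts in self.points.items():
            units = {p.unit for p in pts.values()}
            if units == {"mm"}:
                new_points[view] = dict(pts)
                continue
            if units != {"px"}:
                raise ValidationError(
                    f"subject {self.subject_id!r}: mixed units in the {view} view"
                )
            s = self.view_scale(view)
            new_points[view] = {
                key: Point2(p.u * s, p.v * s, "mm") for key, p in pts.items()
            }
        return replace(self, points=new_points)

    def is_mm(self) -> bool:
        return all(p.unit == "mm" for _, _, _, p in self.iter_points())


@dataclass(frozen=True)
class TranslationResult:
    vertical_mm: float
    vertical_dir: str
    ap_mm: float
    ap_dir: str
    transverse_mm: float
    transverse_dir: str


@dataclass(frozen=True)
class RotationResult:
    sagittal_mm: float
    sagittal_class: str
    inlet_mm: float
    inlet_class: str
    outlet_mm: float
    outlet_class: str
    threshold_mm: float = 2.0


@dataclass(frozen=True)
class DisplacementReport:
    subject_id: str
    injured_side: str
    translation: TranslationResult
    rotation: RotationResult
    scales_mm_per_px: dict[str, float]
    label_convention: str = "table2"


def _ensure_mm(sheet: LandmarkSheet) -> LandmarkSheet:
    return sheet if sheet.is_mm() else sheet.calibrated()


def _direction(kind: str, value: float) -> str:
    neg, none, pos = TRANSLATION_DIRECTIONS[kind]
    if value > 0:
        return pos
    if value < 0:
        return neg
    return none


def _require(sheet: LandmarkSheet, view: str, pairs: list[tuple[str, str]]) -> None:
    missing = [(view, lm, side) for lm, side in pairs if not sheet.has(view, lm, side)]
    if missing:
        raise MissingLandmarkError(missing)


def vertical_displacement(sheet: LandmarkSheet) -> tuple[float, str]:
    """Cephalad/caudad displacement (mm) from the outlet view.

    |v(C') - v(S)| - |v(C) - v(S)| where C is the superior iliac wing point
    and S the sacral endplate centre; positive values are cephalad.
    """
    sheet = _ensure_mm(sheet)
    _require(sheet, "outlet", [("iliac_wing_superior", "intact"),
                               ("iliac_wing_superior", "injured"),
                               ("sacral_endplate_centre", "midline")])
    c = sheet.get("outlet", "iliac_wing_superior", "intact")
    cp = sheet.get("outlet", "iliac_wing_superior", "injured")
    s = sheet.get("outlet", "sacral_endplate_centre", "midline")
    value = abs(cp.v - s.v) - abs(c.v - s.v)
    return value, _direction("vertical", value)


def ap_displacement(sheet: LandmarkSheet) -> tuple[float, str]:
    """Anterior/posterior displacement (mm) from the inlet view.

    |v(H') - v(S)| - |v(H) - v(S)| with H the anterior SI joint (iliac
    side); positive values are anterior.
    """
    sheet = _ensure_mm(sheet)
    _require(sheet, "inlet", [("anterior_SI_joint", "intact"),
                              ("anterior_SI_joint", "injured"),
                              ("sacral_endplate_centre", "midline")])
    h = sheet.get("inlet", "anterior_SI_joint", "intact")
    hp = sheet.get("inlet", "anterior_SI_joint", "injured")
    s = sheet.get("inlet", "sacral_endplate_centre", "midline")
    value = abs(hp.v - s.v) - abs(h.v - s.v)
    return value, _direction("ap", value)


def transverse_displacement(sheet: LandmarkSheet) -> tuple[float, str]:
    """Lateral/medial displacement (mm) from the inlet view.

    |u(H') - u(S)| - |u(H) - u(S)|; positive values are lateral.
    """
    sheet = _ensure_mm(sheet)
    _require(sheet, "inlet", [("anterior_SI_joint", "intact"),
                              ("anterior_SI_joint", "injured"),
                              ("sacral_endplate_centre", "midline")])
    h = sheet.get("inlet", "anterior_SI_joint", "intact")
    hp = sheet.get("inlet", "anterior_SI_joint", "injured")
    s = sheet.get("inlet", "sacral_endplate_centre", "midline")
    value = abs(hp.u - s.u) - abs(h.u - s.u)
    return value, _direction("transverse", value)


_ROTATION_SPEC = {
    # plane -> (view, landmark pair, image coordinate)
    "sagittal": ("ap", ("ASIS", "ischial_tuberosity"), "v"),
    "inlet": ("inlet", ("ASIS", "anterior_SI_joint"), "u"),
    "outlet": ("outlet", ("ASIS", "ischial_tuberosity"), "u"),
}


def rotation_indicator(sheet: LandmarkSheet, plane: str) -> float:
    """Rotational indicator (mm) for a plane: intact-side inter-landmark
    distance minus the injured-side distance, along one image coordinate."""
    if plane not in _ROTATION_SPEC:
        raise ValidationError(f"unknown plane {plane!r}; expected sagittal/inlet/outlet")
    sheet = _ensure_mm(sheet)
    view, (lm1, lm2), coord = _ROTATION_SPEC[plane]
    _require(sheet, view, [(lm1, "intact"), (lm1, "injured"),
                           (lm2, "intact"), (lm2, "injured")])
    a = sheet.get(view, lm1, "intact")
    b = sheet.get(view, lm2, "intact")
    ap_ = sheet.get(view, lm1, "injured")
    bp = sheet.get(view, lm2, "injured")
    idx = 1 if coord == "v" else 0
    return abs(a[idx] - b[idx]) - abs(ap_[idx] - bp[idx])


def classify_rotation(
    indicator_mm: float,
    plane: str,
    threshold_mm: float = 2.0,
    label_convention: str = "table2",
) -> str:
    """Map an indicator to a direction class with an inclusive neutral band.

    ``indicator < -threshold`` and ``indicator > +threshold`` name the two
    rotation directions for the plane; both band edges are neutral.
    """
    if threshold_mm <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold_mm}")
    if label_convention not in ROTATION_CLASSES:
        raise ValidationError(f"unknown label convention {label_convention!r}")
    neg, neutral, pos = ROTATION_CLASSES[label_convention][plane]
    if indicator_mm < -threshold_mm:
        return neg
    if indicator_mm > threshold_mm:
        return pos
    return neutral


def measure_displacement(
    sheet: LandmarkSheet,
    threshold_mm: float = 2.0,
    label_convention: str = "table2",
    allow_partial: bool = False,
) -> DisplacementReport:
    """Full displacement report for one subject.

    Evaluates the three translational formulas and the three rotational
    indicators/classes on a calibrated sheet.  All missing landmarks are
    reported at once; with ``allow_partial`` the affected quantities are NaN
    and their labels ``"unavailable"`` instead.
    """
    sheet = _ensure_mm(sheet)
    missing: list[tuple[str, str, str]] = []
    nan = float("nan")

    def attempt(fn, *args, fallback):
        try:
            return fn(*args)
        except MissingLandmarkError as err:
            missing.extend(err.missing)
            return fallback

    vert = attempt(vertical_displacement, sheet, fallback=(nan, "unavailable"))
    apd = attempt(ap_displacement, sheet, fallback=(nan, "unavailable"))
    trans = attempt(transverse_displacement, sheet, fallback=(nan, "unavailable"))
    indicators = {
        plane: attempt(rotation_indicator, sheet, plane, fallback=nan)
        for plane in ("sagittal", "inlet", "outlet")
    }
    if missing and not allow_partial:
        raise MissingLandmarkError(sorted(set(missing)))

    classes = {
        plane: ("unavailable" if np.isnan(ind)
                else classify_rotation(ind, plane, threshold_mm, label_convention))
        for plane, ind in indicators.items()
    }
    scales = {}
    for view in sheet.points:
        try:
            scales[view] = sheet.view_scale(view)
        except ValidationError:
            scales[view] = 1.0  # sheet authored directly in mm
    return DisplacementReport(
        subject_id=sheet.subject_id,
        injured_side=sheet.injured_side,
        translation=TranslationResult(vert[0], vert[1], apd[0], apd[1], trans[0], trans[1]),
        rotation=RotationResult(
            indicators["sagittal"], classes["sagittal"],
            indicators["inlet"], classes["inlet"],
            indicators["outlet"], classes["outlet"],
            threshold_mm,
        ),
        scales_mm_per_px=scales,
        label_convention=label_convention,
    )
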