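"""Virtual-radiograph study generator with known ground-truth displacement.

A parametric bilateral hemipelvis landmark template stands in for patient
anatomy: one side is rigidly displaced by a known translation + rotation
(the ground truth), the landmark set is orthographically projected into the
standardized inlet/outlet/AP views, and per-rater Gaussian marking noise
emulates independent observers digitising the films.  Measuring the
rendered sheets and comparing against the ground truth closes the loop
that, in the original clinical workflow, required CT-based 3D
reconstruction.

The template coordinates are synthetic engineering values with plausible
adult-pelvis magnitudes (ASIS roughly 115 mm lateral of the midline, the
iliac crest about 4 cm above the sacral endplate centre); they are not
measurements of any real pelvis and can be overridden via configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .coords import (
    RigidTransform,
    ValidationError,
    View,
    apply_rigid,
    project,
    standard_views,
    Point2,
)
from .measurement import Calibration, LandmarkSheet

TEMPLATE_LANDMARKS = ("ASIS", "ischial_tuberosity", "iliac_wing_superior",
                      "anterior_SI_joint", "PSIS")

#: Right-half template coordinates (mm; pelvis frame, +X toward patient left,
#: origin at the sacral endplate centre).  Synthetic values, see module docs.
_HALF_TEMPLATE = {
    "ASIS": (-115.0, 53.0, 88.4),
    "ischial_tuberosity": (-55.0, -134.3, 99.0),
    "iliac_wing_superior": (-85.0, 42.4, -42.4),
    "anterior_SI_joint": (-45.0, -17.7, 31.8),
    "PSIS": (-40.0, -70.7, -49.5),
}
_FH_CENTRE = (-85.0, -42.4, 77.8)
_FH_DIAMETER_MM = 48.0

#: Which template landmarks appear in which radiograph.
VIEW_TEMPLATE_LANDMARKS = {
    "ap": ("ASIS", "ischial_tuberosity"),
    "outlet": ("iliac_wing_superior", "ischial_tuberosity", "ASIS"),
    "inlet": ("ASIS", "anterior_SI_joint"),
}

#: Image-frame offset (px) applied when rendering, so pixel coordinates look
#: like they came from a real detector; all formulas are shift-invariant.
IMAGE_OFFSET_PX = (512.0, 512.0)


def _mirror(p: tuple[float, float, float]) -> tuple[float, float, float]:
    return (-p[0], p[1], p[2])


@dataclass(frozen=True)
class PelvisTemplate:
    """Bilateral 3D landmark set with femoral head geometry.

    ``landmarks`` maps (name, side) -> (x, y, z) mm with side in
    {"left", "right", "midline"}; the sacral endplate centre is the midline
    origin in the undisplaced state.
    """

    landmarks: dict[tuple[str, str], tuple[float, float, float]]
    fh_centre: dict[str, tuple[float, float, float]]
    fh_diameter_mm: float = _FH_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.fh_diameter_mm <= 0:
            raise ValidationError("femoral head diameter must be positive")
        for name in TEMPLATE_LANDMARKS:
            for side in ("left", "right"):
                if (name, side) not in self.landmarks:
                    raise ValidationError(f"template missing landmark {name}/{side}")
        if ("sacral_endplate_centre", "midline") not in self.landmarks:
            raise ValidationError("template missing the sacral endplate centre")

    def side_points(self, side: str, names=TEMPLATE_LANDMARKS) -> np.ndarray:
        return np.array([self.landmarks[(n, side)] for n in names], float)

    def centroid(self, side: str) -> np.ndarray:
        return self.side_points(side).mean(axis=0)


def default_template(overrides: dict | None = None) -> PelvisTemplate:
    """The shipped mirror-symmetric template.

    ``overrides`` may replace individual right-side landmark coordinates
    (``{"ASIS": (x, y, z), ...}``); the left side mirrors them in X.
    """
    half = dict(_HALF_TEMPLATE)
    fh = _FH_CENTRE
    diameter = _FH_DIAMETER_MM
    if overrides:
        for name, value in overrides.items():
            if name == "femoral_head_centre":
                fh = tuple(float(v) for v in value)
            elif name == "femoral_head_diameter_mm":
                diameter = float(value)
            elif name in half:
                half[name] = tuple(float(v) for v in value)
            else:
                raise ValidationError(f"unknown template landmark {name!r}")
    landmarks: dict[tuple[str, str], tuple[float, float, float]] = {
        ("sacral_endplate_centre", "midline"): (0.0, 0.0, 0.0)
    }
    for name, p in half.items():
        landmarks[(name, "right")] = p
        landmarks[(name, "left")] = _mirror(p)
    return PelvisTemplate(
        landmarks=landmarks,
        fh_centre={"right": fh, "left": _mirror(fh)},
        fh_diameter_mm=diameter,
    )


PIVOT_CHOICES = ("centroid", "si_joint", "acetabulum")


@dataclass(frozen=True)
class DisplacementSpec:
    """Ground-truth rigid displacement of the injured hemipelvis.

    Translations are world-frame mm.  Rotation angles are named
    anatomically and converted to signed world rotations per side:

    * ``rot_x_deg`` — sagittal plane: positive = extension, negative = flexion;
    * ``rot_y_deg`` — inlet plane: positive = internal, negative = external;
    * ``rot_z_deg`` — outlet plane: positive = varus, negative = valgus.

    (Direction names follow the canonical measurement-table convention.)
    ``pivot`` is one of :data:`PIVOT_CHOICES` or an explicit (x, y, z).
    """

    injured_side: str
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rot_x_deg: float = 0.0
    rot_y_deg: float = 0.0
    rot_z_deg: float = 0.0
    pivot: str | tuple[float, float, float] = "centroid"

    def __post_init__(self) -> None:
        if self.injured_side not in ("left", "right"):
            raise ValidationError(f"injured_side must be left/right, got {self.injured_side!r}")
        if isinstance(self.pivot, str) and self.pivot not in PIVOT_CHOICES:
            raise ValidationError(f"pivot must be one of {PIVOT_CHOICES} or coordinates")

    @property
    def side_sign(self) -> float:
        """+1 for a left (+X) injured hemipelvis, -1 for a right one."""
        return 1.0 if self.injured_side == "left" else -1.0

    def resolve_pivot(self, template: PelvisTemplate) -> np.ndarray:
        if not isinstance(self.pivot, str):
            return np.asarray(self.pivot, float)
        if self.pivot == "centroid":
            return template.centroid(self.injured_side)
        if self.pivot == "si_joint":
            return np.asarray(template.landmarks[("anterior_SI_joint", self.injured_side)], float)
        return np.asarray(template.fh_centre[self.injured_side], float)

    def to_transform(self, template: PelvisTemplate) -> RigidTransform:
        """World-frame rigid transform realising the named displacement.

        Internal/external and varus/valgus are mirror-antisymmetric: the
        same anatomical direction corresponds to opposite signed world
        rotations on the two sides.  Flexion/extension is side-symmetric.
        """
        s = self.side_sign
        return RigidTransform(
            rot_x_deg=self.rot_x_deg,
            rot_y_deg=-s * self.rot_y_deg,
            rot_z_deg=s * self.rot_z_deg,
            pivot=tuple(self.resolve_pivot(template)),
            translation=(self.tx, self.ty, self.tz),
        )

    @property
    def is_zero(self) -> bool:
        return all(v == 0 for v in (self.tx, self.ty, self.tz,
                                    self.rot_x_deg, self.rot_y_deg, self.rot_z_deg))


def displace(template: PelvisTemplate, spec: DisplacementSpec) -> PelvisTemplate:
    """Apply the ground-truth displacement to the injured side only."""
    t = spec.to_transform(template)
    side = spec.injured_side
    names = list(TEMPLATE_LANDMARKS)
    moved = apply_rigid(template.side_points(side, names), t)
    new_landmarks = dict(template.landmarks)
    for name, p in zip(names, moved):
        new_landmarks[(name, side)] = tuple(p)
    new_fh = dict(template.fh_centre)
    new_fh[side] = tuple(apply_rigid([template.fh_centre[side]], t)[0])
    return replace(template, landmarks=new_landmarks, fh_centre=new_fh)


def render_sheets(
    template: PelvisTemplate,
    injured_side: str,
    subject_id: str,
    views: dict[str, View] | None = None,
    mm_per_px: float = 0.5,
) -> LandmarkSheet:
    """Project a (possibly displaced) template into the three views.

    Returns a pixel-unit sheet carrying per-view calibration: the intact
    femoral head is rendered as a diameter line (d1, d2) whose pixel length
    equals the true diameter divided by ``mm_per_px``.
    """
    if mm_per_px <= 0:
        raise ValidationError("mm_per_px must be positive")
    views = views or standard_views()
    intact = "right" if injured_side == "left" else "left"
    du, dv = IMAGE_OFFSET_PX
    points: dict[str, dict[tuple[str, str], Point2]] = {}
    calibration: dict[str, Calibration] = {}
    for view_name, view in views.items():
        entries: list[tuple[str, str, tuple[float, float, float]]] = []
        for lm in VIEW_TEMPLATE_LANDMARKS[view_name]:
            entries.append((lm, "intact", template.landmarks[(lm, intact)]))
            entries.append((lm, "injured", template.landmarks[(lm, injured_side)]))
        if view_name in ("inlet", "outlet"):
            entries.append(("sacral_endplate_centre", "midline",
                            template.landmarks[("sacral_endplate_centre", "midline")]))
        uv = project([p for _, _, p in entries], view) / mm_per_px
        uv += np.array([du, dv])
        view_points = {
            (lm, side): Point2(float(u), float(v), "px")
            for (lm, side, _), (u, v) in zip(entries, uv)
        }
        # Intact femoral head diameter rendered along the image u-axis.
        fh_uv = project([template.fh_centre[intact]], view)[0] / mm_per_px + [du, dv]
        half_px = template.fh_diameter_mm / 2.0 / mm_per_px
        view_points[("femoral_head_d1", "intact")] = Point2(
            float(fh_uv[0] - half_px), float(fh_uv[1]), "px")
        view_points[("femoral_head_d2", "intact")] = Point2(
            float(fh_uv[0] + half_px), float(fh_uv[1]), "px")
        points[view_name] = view_points
        calibration[view_name] = Calibration(
            fh_true_mm=template.fh_diameter_mm,
            fh_px=template.fh_diameter_mm / mm_per_px,
        )
    return LandmarkSheet(subject_id, injured_side, points, calibration)


def add_marking_noise(
    sheet: LandmarkSheet,
    sd_mm: float,
    rng: np.random.Generator | int,
    recalibrate_from_marks: bool = False,
) -> LandmarkSheet:
    """Independent isotropic Gaussian perturbation of every 2D landmark.

    ``sd_mm`` is the observer's marking error as the RMS of the 2D miss
    distance (the fiducial-localization-error convention), so each image
    coordinate is perturbed with standard deviation ``sd_mm / sqrt(2)``.
    Coordinates are converted with each view's scale when the sheet is in
    pixels.

    By default the calibration record is left untouched, mirroring a
    standardized workflow in which the pixel-mm relationship is established
    once per image rather than by each observer; with
    ``recalibrate_from_marks`` the femoral-head pixel diameter is instead
    re-measured from the perturbed diameter marks, so observer calibration
    error propagates into the mm values.
    """
    if sd_mm < 0:
        raise ValidationError("noise SD must be non-negative")
    if sd_mm == 0:
        return sheet
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    sd_axis_mm = sd_mm / np.sqrt(2.0)
    new_points: dict[str, dict[tuple[str, str], Point2]] = {}
    new_cal = dict(sheet.calibration)
    for view, pts in sheet.points.items():
        in_px = next(iter(pts.values())).unit == "px"
        sd = sd_axis_mm / sheet.view_scale(view) if in_px else sd_axis_mm
        keys = sorted(pts)  # stable perturbation order for reproducibility
        noise = rng.normal(0.0, sd, size=(len(keys), 2))
        view_pts = {
            key: Point2(pts[key].u + e[0], pts[key].v + e[1], pts[key].unit)
            for key, e in zip(keys, noise)
        }
        new_points[view] = view_pts
        d1 = view_pts.get(("femoral_head_d1", "intact"))
        d2 = view_pts.get(("femoral_head_d2", "intact"))
        if recalibrate_from_marks and d1 is not None and d2 is not None and view in new_cal:
            fh_px = float(np.hypot(d1.u - d2.u, d1.v - d2.v))
            new_cal[view] = Calibration(new_cal[view].fh_true_mm, fh_px)
    return replace(sheet, points=new_points, calibration=new_cal)


@dataclass(frozen=True)
class DisplacementDistribution:
    """Mixture of unstable-injury displacement patterns.

    Subjects are drawn either translation-dominant (vertical-shear-like,
    "type C") or rotation-dominant ("type B").  All components are
    truncated zero-mean Gaussians: the dominant pattern uses the larger SD
    for its emphasised quantity and the smaller SD for the other, so with
    equal weights the pooled SDs are close to 10 mm for translations and
    8 degrees for rotations — the displacement regime the study targets —
    while individual subjects still look shear-like or rotation-like.
    """

    p_translation_dominant: float = 0.5
    trans_sd_dominant: float = 12.0
    trans_sd_other: float = 8.0
    trans_cap: float = 30.0
    rot_sd_dominant: float = 10.0
    rot_sd_other: float = 5.0
    rot_cap: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_translation_dominant <= 1.0):
            raise ValidationError("mixture weight must lie in [0, 1]")
        sds = (self.trans_sd_dominant, self.trans_sd_other,
               self.rot_sd_dominant, self.rot_sd_other)
        if min(sds) < 0:
            raise ValidationError("distribution SDs must be non-negative")

    @property
    def is_degenerate(self) -> bool:
        return max(self.trans_sd_dominant, self.trans_sd_other,
                   self.rot_sd_dominant, self.rot_sd_other) == 0

    def _trunc(self, rng: np.random.Generator, sd: float, cap: float, size: int):
        if sd == 0:
            return np.zeros(size)
        a = -cap / sd
        return stats.truncnorm.rvs(a, -a, scale=sd, size=size, random_state=rng)

    def sample(self, rng: np.random.Generator, injured_side: str,
               pivot: str = "centroid") -> DisplacementSpec:
        translation_dominant = rng.random() < self.p_translation_dominant
        if translation_dominant:
            t_sd, r_sd = self.trans_sd_dominant, self.rot_sd_other
        else:
            t_sd, r_sd = self.trans_sd_other, self.rot_sd_dominant
        tx, ty, tz = self._trunc(rng, t_sd, self.trans_cap, 3)
        rx, ry, rz = self._trunc(rng, r_sd, self.rot_cap, 3)
        return DisplacementSpec(injured_side, tx, ty, tz, rx, ry, rz, pivot)


@dataclass(frozen=True)
class SimulatedSubject:
    subject_id: str
    spec: DisplacementSpec
    sheet: LandmarkSheet  # noiseless rendering


@dataclass(frozen=True)
class SimulatedStudy:
    subjects: tuple[SimulatedSubject, ...]
    rater_sheets: dict[str, list[LandmarkSheet]]
    seed: int
    noise_sd_mm: float
    mm_per_px: float

    @property
    def rater_ids(self) -> list[str]:
        return sorted(self.rater_sheets)


def simulate_study(
    n_subjects: int = 25,
    n_raters: int = 5,
    noise_sd_mm: float = 1.0,
    seed: int = 0,
    distribution: DisplacementDistribution | None = None,
    template: PelvisTemplate | None = None,
    views: dict[str, View] | None = None,
    mm_per_px: float = 0.5,
    pivot: str = "centroid",
) -> SimulatedStudy:
    """Generate a full in-silico reliability study.

    Each subject gets a displacement drawn from ``distribution`` applied to
    a random side, a noiseless rendered sheet, and one independently
    perturbed sheet per rater.  Rater noise streams are spawned from the
    global seed, so the whole study is reproducible bit-for-bit.
    """
    if n_subjects < 2 or n_raters < 2:
        raise ValidationError("need at least 2 subjects and 2 raters")
    distribution = distribution or DisplacementDistribution()
    if distribution.is_degenerate:
        import warnings

        warnings.warn("degenerate displacement distribution: all subjects undisplaced",
                      stacklevel=2)
    template = template or default_template()
    views = views or standard_views()
    ss = np.random.SeedSequence(seed)
    subject_seed, *rater_seeds = ss.spawn(1 + n_raters)
    rng = np.random.default_rng(subject_seed)

    subjects = []
    for i in range(n_subjects):
        side = "left" if rng.random() < 0.5 else "right"
        spec = distribution.sample(rng, side, pivot)
        sheet = render_sheets(displace(template, spec), side, f"S{i + 1:03d}",
                              views, mm_per_px)
        subjects.append(SimulatedSubject(sheet.subject_id, spec, sheet))

    rater_sheets = {}
    for k, rseed in enumerate(rater_seeds, start=1):
        rrng = np.random.default_rng(rseed)
        rater_sheets[f"rater{k}"] = [
            add_marking_noise(subj.sheet, noise_sd_mm, rrng) for subj in subjects
        ]
    return SimulatedStudy(tuple(subjects), rater_sheets, seed, noise_sd_mm, mm_per_px)


# ---------------------------------------------------------------------------
# Recovery evaluation against ground truth


def true_translations(spec: DisplacementSpec) -> dict[str, float]:
    """Ground-truth translations on the measurement scale: positive values
    are cephalad / anterior / lateral (transverse is mirror-antisymmetric)."""
    return {"vertical": spec.ty, "ap": spec.tz, "transverse": spec.side_sign * spec.tx}


def _true_angle(spec: DisplacementSpec, plane: str) -> float:
    return {"sagittal": spec.rot_x_deg, "inlet": spec.rot_y_deg,
            "outlet": spec.rot_z_deg}[plane]


def true_rotation_class(
    spec: DisplacementSpec, noiseless_sheet: LandmarkSheet, plane: str,
    threshold_mm: float = 2.0,
) -> str:
    """Ground-truth rotation class for a plane.

    A subject whose true angle about the plane's axis is exactly zero is
    neutral, unless cross-axis coupling pushes even its noiseless indicator
    outside the band, in which case the indicator's class is the truth.
    Nonzero angles are named by their sign.
    """
    from .measurement import classify_rotation, rotation_indicator
    from .measurement import ROTATION_CLASSES

    angle = _true_angle(spec, plane)
    if angle == 0:
        ind = rotation_indicator(noiseless_sheet, plane)
        return classify_rotation(ind, plane, threshold_mm)
    neg, _, pos = ROTATION_CLASSES["table2"][plane]
    return pos if angle > 0 else neg


@dataclass(frozen=True)
class ParameterRecovery:
    bias_mm: float
    rmse_mm: float
    n: int


@dataclass(frozen=True)
class RecoveryReport:
    """Measurement accuracy of a study against its ground truth."""

    translation: dict[str, ParameterRecovery]
    confusion: dict[str, "object"]  # plane -> true-class x measured-class DataFrame
    accuracy: dict[str, float]
    overall_accuracy: float


def evaluate_recovery(
    study: SimulatedStudy,
    reports_by_rater: dict[str, dict[str, "object"]],
    threshold_mm: float = 2.0,
) -> RecoveryReport:
    """Bias/RMSE of the translational measurements and confusion matrices of
    the rotational classes versus ground truth, pooled over all raters."""
    import pandas as pd

    from .measurement import ROTATION_CLASSES
    from .reliability import ROTATION_PLANES

    subject_ids = [s.subject_id for s in study.subjects]
    for rater, reports in reports_by_rater.items():
        missing = sorted(set(subject_ids) - set(reports))
        extra = sorted(set(reports) - set(subject_ids))
        if missing or extra:
            raise ValidationError(
                f"rater {rater!r}: subject set mismatch "
                f"(missing {missing or 'none'}, unexpected {extra or 'none'})"
            )

    by_id = {s.subject_id: s for s in study.subjects}
    translation = {}
    for param in ("vertical", "ap", "transverse"):
        errors = []
        for reports in reports_by_rater.values():
            for sid in subject_ids:
                rep = reports[sid]
                measured = {"vertical": rep.translation.vertical_mm,
                            "ap": rep.translation.ap_mm,
                            "transverse": rep.translation.transverse_mm}[param]
                errors.append(measured - true_translations(by_id[sid].spec)[param])
        errors = np.asarray(errors)
        translation[param] = ParameterRecovery(
            float(errors.mean()), float(np.sqrt(np.mean(errors**2))), len(errors))

    confusion = {}
    accuracy = {}
    hits = total = 0
    for plane in ROTATION_PLANES:
        neg, neutral, pos = ROTATION_CLASSES["table2"][plane]
        classes = [neg, neutral, pos]
        counts = pd.DataFrame(0, index=classes, columns=classes)
        truth = {
            sid: true_rotation_class(by_id[sid].spec, by_id[sid].sheet, plane, threshold_mm)
            for sid in subject_ids
        }
        for reports in reports_by_rater.values():
            for sid in subject_ids:
                measured = {"sagittal": reports[sid].rotation.sagittal_class,
                            "inlet": reports[sid].rotation.inlet_class,
                            "outlet": reports[sid].rotation.outlet_class}[plane]
                counts.loc[truth[sid], measured] += 1
        confusion[plane] = counts
        diag = float(np.trace(counts.to_numpy()))
        accuracy[plane] = diag / counts.to_numpy().sum()
        hits += diag
        total += counts.to_numpy().sum()
    return RecoveryReport(translation, confusion, accuracy, float(hits / total))
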