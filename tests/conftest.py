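import numpy as np
import pytest

from pelvimetrix.coords import Point2
from pelvimetrix.measurement import LandmarkSheet


@pytest.fixture
def mm_sheet_factory():
    """Build a LandmarkSheet directly in mm from per-view coordinate dicts.

    Usage: factory(ap={("ASIS", "intact"): (u, v), ...}, outlet=..., inlet=...)
    """

    def factory(subject_id="T1", injured_side="left", **views):
        points = {
            view: {key: Point2(float(u), float(v), "mm") for key, (u, v) in pts.items()}
            for view, pts in views.items()
        }
        return LandmarkSheet(subject_id, injured_side, points)

    return factory


@pytest.fixture
def symmetric_sheet(mm_sheet_factory):
    """A bilaterally symmetric, undisplaced subject: every formula is zero."""
    return mm_sheet_factory(
        ap={("ASIS", "intact"): (-100, 50), ("ASIS", "injured"): (100, 50),
            ("ischial_tuberosity", "intact"): (-50, -80),
            ("ischial_tuberosity", "injured"): (50, -80)},
        outlet={("iliac_wing_superior", "intact"): (-85, 42),
                ("iliac_wing_superior", "injured"): (85, 42),
                ("ischial_tuberosity", "intact"): (-55, -134),
                ("ischial_tuberosity", "injured"): (55, -134),
                ("ASIS", "intact"): (-115, 53), ("ASIS", "injured"): (115, 53),
                ("sacral_endplate_centre", "midline"): (0, 0)},
        inlet={("ASIS", "intact"): (-115, 88), ("ASIS", "injured"): (115, 88),
               ("anterior_SI_joint", "intact"): (-45, 32),
               ("anterior_SI_joint", "injured"): (45, 32),
               ("sacral_endplate_centre", "midline"): (0, 0)},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
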