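import dataclasses

import numpy as np
import pytest

from facemetrics import (
    CohortSpec,
    LandmarkSet,
    make_calibration,
)


def zero_sd(spec: CohortSpec, **overrides) -> CohortSpec:
    """Copy a cohort spec with every SD forced to zero and fixed transforms."""
    kwargs = {}
    for f in dataclasses.fields(spec):
        v = getattr(spec, f.name)
        if isinstance(v, tuple) and len(v) == 2 and f.name not in ("scale_range", "rotation_range"):
            kwargs[f.name] = (v[0], 0.0)
    kwargs["scale_range"] = (10.0, 10.0)
    kwargs["rotation_range"] = (0.0, 0.0)
    kwargs["wtw_mm"] = (11.71, 0.0)
    kwargs.update(overrides)
    return dataclasses.replace(spec, **kwargs)


@pytest.fixture
def calib_01mm():
    """Calibration where 1 px = 0.1 mm (WTW of 117.1 px at the default reference)."""
    return make_calibration(117.1)


def simple_eyes(tilt_px: float = 0.0) -> LandmarkSet:
    """Four canthi spanning x = 200..1200 with the documented 0.311/0.374/0.315 split."""
    ls = LandmarkSet("eyes")
    ls.add("exocanthion_R", 200.0, 900.0 - tilt_px)
    ls.add("endocanthion_R", 511.0, 900.0)
    ls.add("endocanthion_L", 885.0, 900.0)
    ls.add("exocanthion_L", 1200.0, 900.0 - tilt_px)
    return ls


def rotate_landmarks(ls: LandmarkSet, theta_deg: float, center=(0.0, 0.0)) -> LandmarkSet:
    """Rigid visually-clockwise rotation of every landmark about ``center``."""
    c = np.cos(np.radians(theta_deg))
    s = np.sin(np.radians(theta_deg))
    cx, cy = center
    out = LandmarkSet(ls.subject_id)
    for name, p in ls.points.items():
        dx, dy = p.x - cx, p.y - cy
        out.add(name, cx + dx * c + dy * s, cy - dx * s + dy * c)
    return out
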