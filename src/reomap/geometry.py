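"""Chamber geometry constants and coordinate helpers.

The rectangular chamber is 20 cm x 30 cm.  Native rate maps use 1 cm x 1 cm
pixels (20 x 30 bins); "square" maps use anisotropic 1 cm x 1.5 cm bins so
both axes carry 20 bins, which makes quarter-turn rotations well defined.

Array convention: grids are indexed ``[row, col]`` with row = y bin and
col = x bin, origin at the chamber corner (x=0, y=0).  Angles follow the
mathematical convention: 0 deg toward +x, counterclockwise, in [0, 360).
"""
from __future__ import annotations

import numpy as np

# Chamber extent (cm).  The 2:3 aspect ratio is what makes the anisotropic
# compression land exactly on a 20 x 20 grid.
CHAMBER_X_CM = 20.0
CHAMBER_Y_CM = 30.0

# Native binning: 1 cm isotropic pixels.
BIN_CM = 1.0
NX = 20
NY = 30

# Square compression: x stays at 1 cm, y is squeezed into 1.5 cm bins.
SQUARE_N = 20
SQUARE_BIN_Y_CM = 1.5

CHAMBER_CENTER = (CHAMBER_X_CM / 2.0, CHAMBER_Y_CM / 2.0)

#: Canonical chamber corners, counterclockwise from the origin.
CANONICAL_CORNERS = np.array(
    [
        [0.0, 0.0],
        [CHAMBER_X_CM, 0.0],
        [CHAMBER_X_CM, CHAMBER_Y_CM],
        [0.0, CHAMBER_Y_CM],
    ]
)


def rotate_about_center(xy: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate points about the chamber center.

    Only 0 and 180 keep the rectangle onto itself; other angles are allowed
    here (callers validate where the geometric symmetry matters).
    """
    arr = np.asarray(xy, dtype=float)
    single = arr.ndim == 1
    pts = np.atleast_2d(arr)
    cx, cy = CHAMBER_CENTER
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    dx, dy = pts[:, 0] - cx, pts[:, 1] - cy
    out = np.column_stack([cx + c * dx - s * dy, cy + s * dx + c * dy])
    return out[0] if single else out


def fold_into_interval(p: np.ndarray, length: float) -> np.ndarray:
    """Reflectively fold unbounded coordinates into ``[0, length]``.

    Equivalent to specular reflection at both walls (triangle-wave map),
    which preserves local speeds away from the walls.
    """
    q = np.mod(p, 2.0 * length)
    return length - np.abs(length - q)


def wrap_deg(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles (degrees) into [0, 360)."""
    return np.mod(a, 360.0)
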