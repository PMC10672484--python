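"""Acetabular index geometry on anteroposterior pelvic radiographs.

The acetabular index (AcI) quantifies the inclination of the acetabular
roof in infants.  It is measured on an AP radiograph from four landmarks:
the two triradiate cartilage centres, which define the Hilgenreiner
reference line (H-line), and the two lateral acetabular edges, which
together with the triradiate points define the left and right acetabular
roof lines.  The AcI of one side is the acute angle between the H-line and
that side's roof line; values well above ~30 degrees in infancy indicate
developmental dysplasia of the hip (DDH).

Coordinates are image pixels: x grows rightward, y grows downward,
0-based.  "Left"/"right" refer to position in the image (the convention
used by the annotation labels), not patient anatomy.

The angle is computed as ``atan2(|det(h, m)|, |h . m|)`` for H-line vector
``h`` and roof vector ``m``, which yields the acute angle between the two
*lines* in [0, 90] degrees independently of the orientation chosen for
either vector.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import DegenerateLandmarksError, InvalidThresholdError

__all__ = [
    "Point2D",
    "LandmarkSet",
    "AcIMeasurement",
    "DiagnosisResult",
    "LANDMARK_NAMES",
    "hilgenreiner_vector",
    "roof_vector",
    "compute_aci",
    "classify_ddh",
]

#: Canonical landmark order used throughout the package and in COCO files.
LANDMARK_NAMES = ("RU", "RD", "LU", "LD")


@dataclass(frozen=True)
class Point2D:
    """A continuous pixel coordinate (x = column, y = row)."""

    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"Point2D requires finite coordinates, got ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def __iter__(self) -> Iterator[float]:
        yield self.x
        yield self.y


def _as_point(p) -> Point2D:
    if isinstance(p, Point2D):
        return p
    x, y = p
    return Point2D(float(x), float(y))


@dataclass(frozen=True)
class LandmarkSet:
    """The four AcI landmarks of one radiograph.

    Attributes
    ----------
    RU, RD : Point2D
        Right-side (image space) lateral acetabular edge and triradiate
        cartilage centre.
    LU, LD : Point2D
        Left-side lateral acetabular edge and triradiate cartilage centre.
    """

    RU: Point2D
    RD: Point2D
    LU: Point2D
    LD: Point2D

    def __post_init__(self):
        for name in LANDMARK_NAMES:
            object.__setattr__(self, name, _as_point(getattr(self, name)))

    def __iter__(self) -> Iterator[Point2D]:
        return iter(self.as_tuple())

    def as_tuple(self) -> tuple[Point2D, Point2D, Point2D, Point2D]:
        return (self.RU, self.RD, self.LU, self.LD)

    def as_array(self) -> np.ndarray:
        """(4, 2) float array in canonical (RU, RD, LU, LD) order."""
        return np.array([list(p) for p in self.as_tuple()], dtype=float)

    def to_json(self) -> str:
        return json.dumps({n: list(getattr(self, n)) for n in LANDMARK_NAMES}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LandmarkSet":
        rec = json.loads(text)
        return cls(**{n: _as_point(rec[n]) for n in LANDMARK_NAMES})

    @classmethod
    def from_array(cls, arr) -> "LandmarkSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (4, 2):
            raise ValueError(f"expected (4, 2) array, got {arr.shape}")
        return cls(*(Point2D(*row) for row in arr))


@dataclass(frozen=True)
class AcIMeasurement:
    """Per-side acetabular index angles in decimal degrees, each in [0, 90]."""

    right_deg: float
    left_deg: float

    def __post_init__(self):
        for v in (self.right_deg, self.left_deg):
            if not (0.0 <= v <= 90.0):
                raise ValueError(f"AcI angle {v} outside [0, 90] degrees")

    def side(self, side: str) -> float:
        return {"right": self.right_deg, "left": self.left_deg}[side]


@dataclass(frozen=True)
class DiagnosisResult:
    """Threshold-based DDH call per side and overall."""

    right_label: str
    left_label: str
    overall_label: str
    threshold_deg: float


def hilgenreiner_vector(lm: LandmarkSet) -> np.ndarray:
    """Displacement vector of the Hilgenreiner line, LD - RD.

    Raises
    ------
    DegenerateLandmarksError
        If the two triradiate points coincide.
    """
    v = lm.LD.as_array() - lm.RD.as_array()
    if not v.any():
        raise DegenerateLandmarksError("RD == LD: Hilgenreiner line undefined")
    return v


def roof_vector(lm: LandmarkSet, side: str) -> np.ndarray:
    """Acetabular roof vector for one side, U - D (triradiate -> lateral edge)."""
    if side == "right":
        u, d = lm.RU, lm.RD
    elif side == "left":
        u, d = lm.LU, lm.LD
    else:
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    v = u.as_array() - d.as_array()
    if not v.any():
        raise DegenerateLandmarksError(f"{side} roof line undefined: U == D")
    return v


def _line_angle_deg(h: np.ndarray, m: np.ndarray) -> float:
    # acute angle between the *lines* spanned by h and m, in [0, 90]
    det = h[0] * m[1] - h[1] * m[0]
    dot = float(h @ m)
    return math.degrees(math.atan2(abs(det), abs(dot)))


def compute_aci(lm: LandmarkSet) -> AcIMeasurement:
    """Acetabular index of both sides, in degrees.

    The result is invariant under rigid transforms and uniform scaling of
    the landmark set, and under reversal of any vector's orientation.
    """
    h = hilgenreiner_vector(lm)
    return AcIMeasurement(
        right_deg=_line_angle_deg(h, roof_vector(lm, "right")),
        left_deg=_line_angle_deg(h, roof_vector(lm, "left")),
    )


def classify_ddh(m: AcIMeasurement, threshold_deg: float = 30.0) -> DiagnosisResult:
    """Label each side 'ddh' iff its AcI is >= threshold (boundary inclusive).

    The overall label is 'ddh' iff at least one side is. The default 30
    degree threshold matches the mean AcI of the dysplastic class in
    infant screening populations and is always overridable.
    """
    if not (0.0 < threshold_deg < 90.0):
        raise InvalidThresholdError(f"threshold {threshold_deg} outside (0, 90) degrees")
    right = "ddh" if m.right_deg >= threshold_deg else "normal"
    left = "ddh" if m.left_deg >= threshold_deg else "normal"
    overall = "ddh" if "ddh" in (right, left) else "normal"
    return DiagnosisResult(right, left, overall, threshold_deg)
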