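"""Virtual-facebow geometry on a lateral cephalogram.

A semi-adjustable articulator mounts the maxillary model against the
axis-orbital plane (AOP) and the arbitrary hinge axis.  The same mounting can
be derived virtually from four landmarks on a lateral cephalogram: porion
inferior (Pi), the nasal facebow support (Ns), the upper incisor edge (Ie) and
the distobuccal cusp of the first upper molar (Dc).  From these, together with
the physical facebow dimensions, this module constructs the AOP, places the
arbitrary hinge axis Ax, and measures the mounting triple

    alpha  - angle between the upper occlusal plane (Ie-Dc) and the AOP,
    AxV    - perpendicular distance from Ax to the occlusal plane,
    AxH    - distance along the occlusal plane from Ie to the foot point Ax'.

Coordinate convention (right-lateral view): x anterior-positive, y
superior-positive.  Angles are degrees at every interface, radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "CephLandmarks",
    "FacebowSpec",
    "MountingValues",
    "DerivedArticulatorValues",
    "AOPLine",
    "LandmarkLayout",
    "DegenerateScalingError",
    "InfeasibleFacebowError",
    "calibrate",
    "construct_aop",
    "hinge_axis_position",
    "compute_mounting",
    "invert_mounting",
    "decalibrate",
    "transform_landmarks",
    "derive_articulator_values",
    "round_half_up",
    "round_presets",
    "BONWILL_NORM_MM",
    "BALKWILL_NORM_RANGE_DEG",
]

#: Norm length of one arm of the Bonwill triangle (condylar midpoint to lower
#: incisor contact point), mm.
BONWILL_NORM_MM = 101.6

#: Norm range of the Balkwill angle (occlusal plane vs. Bonwill plane), degrees.
BALKWILL_NORM_RANGE_DEG = (18.0, 25.0)


class DegenerateScalingError(ValueError):
    """The scaling reference pair Ref0/Ref1 coincides."""


class InfeasibleFacebowError(ValueError):
    """No facebow construction exists for the given landmarks/dimensions."""


def _cross2(a: np.ndarray, b: np.ndarray) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _pt(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected a 2D point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite coordinate")
    return a


@dataclass(frozen=True)
class CephLandmarks:
    """Named 2D landmarks from one lateral cephalogram plus a scaling pair.

    ``Ref0``/``Ref1`` are radio-opaque markers a known physical distance
    ``ref_distance_mm`` apart; :func:`calibrate` uses them to convert pixel
    coordinates to millimetres.  ``calibrated`` flags mm-scale coordinates.
    """

    Pi: np.ndarray
    Ns: np.ndarray
    Ie: np.ndarray
    Dc: np.ndarray
    Ref0: np.ndarray
    Ref1: np.ndarray
    ref_distance_mm: float
    calibrated: bool = False

    def __post_init__(self):
        for name in ("Pi", "Ns", "Ie", "Dc", "Ref0", "Ref1"):
            object.__setattr__(self, name, _pt(getattr(self, name)))
        if self.ref_distance_mm <= 0:
            raise ValueError("ref_distance_mm must be positive")
        if np.allclose(self.Ie, self.Dc):
            raise ValueError("Ie and Dc coincide: occlusal plane undefined")
        if np.allclose(self.Ref0, self.Ref1):
            raise DegenerateScalingError("Ref0 and Ref1 coincide")

    def points(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in ("Pi", "Ns", "Ie", "Dc", "Ref0", "Ref1")}


@dataclass(frozen=True)
class FacebowSpec:
    """Physical dimensions of the facebow closing the construction.

    d_ns_mm
        Perpendicular distance of the nasal support Ns above the axis-orbital
        line.
    ax_offset_along_mm, ax_offset_perp_mm
        Placement of the arbitrary hinge axis Ax relative to the AOP anchor
        (the Pi-derived point), along the AOP (anterior-positive) and
        perpendicular to it (superior-positive).
    """

    d_ns_mm: float
    ax_offset_along_mm: float = 0.0
    ax_offset_perp_mm: float = 0.0

    def __post_init__(self):
        if not all(
            math.isfinite(v)
            for v in (self.d_ns_mm, self.ax_offset_along_mm, self.ax_offset_perp_mm)
        ):
            raise ValueError("facebow dimensions must be finite")
        if self.d_ns_mm < 0:
            raise ValueError("d_ns_mm must be >= 0")


@dataclass(frozen=True)
class MountingValues:
    """The triple (alpha, AxV, AxH) positioning the maxilla vs. the hinge axis.

    ``alpha_deg`` is stored signed (positive when the occlusal plane ascends
    posteriorly toward the AOP); printed summaries may aggregate signed values.
    """

    alpha_deg: float
    axv_mm: float
    axh_mm: float

    def __post_init__(self):
        if not all(
            math.isfinite(v) for v in (self.alpha_deg, self.axv_mm, self.axh_mm)
        ):
            raise ValueError("mounting values must be finite")
        if abs(self.alpha_deg) >= 90:
            raise ValueError("|alpha_deg| must be < 90")
        if self.axv_mm < 0:
            raise ValueError("axv_mm must be >= 0")
        if self.axh_mm <= 0:
            raise ValueError("axh_mm must be > 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha_deg, self.axv_mm, self.axh_mm)


@dataclass(frozen=True)
class DerivedArticulatorValues:
    """Bonwill-arm / Balkwill-angle equivalents of a mounting triple."""

    ie_ax_mm: float
    balkwill_deg: float
    bonwill_norm_mm: float = BONWILL_NORM_MM
    balkwill_norm_range_deg: tuple[float, float] = BALKWILL_NORM_RANGE_DEG


@dataclass(frozen=True)
class AOPLine:
    """The axis-orbital line: anchor point, anterior unit direction, foot b."""

    anchor: np.ndarray
    direction: np.ndarray  # unit, anterior-pointing
    b: np.ndarray  # foot of the perpendicular from Ns

    @property
    def normal(self) -> np.ndarray:
        """Unit normal, superior-pointing when direction points anteriorly."""
        return np.array([-self.direction[1], self.direction[0]])


def calibrate(landmarks: CephLandmarks) -> CephLandmarks:
    """Scale all landmark coordinates to millimetres.

    Multiplies every point by ``ref_distance_mm / |Ref0 - Ref1|``.  The
    operation is idempotent in effect when the pixel spacing already equals
    1 mm.  Raises :class:`DegenerateScalingError` for a coincident pair.
    """
    span = float(np.linalg.norm(landmarks.Ref1 - landmarks.Ref0))
    if span == 0.0:
        raise DegenerateScalingError("Ref0 and Ref1 coincide")
    s = landmarks.ref_distance_mm / span
    scaled = {n: p * s for n, p in landmarks.points().items()}
    return CephLandmarks(
        **scaled, ref_distance_mm=landmarks.ref_distance_mm, calibrated=True
    )


def construct_aop(landmarks: CephLandmarks, facebow: FacebowSpec) -> AOPLine:
    """Construct the axis-orbital line from Pi and the nasal support Ns.

    The line passes through the Pi anchor and runs at perpendicular distance
    ``d_ns_mm`` below the nasal support; ``b`` is the foot of the
    perpendicular from Ns.  Of the two tangent solutions the anatomically
    oriented one is returned: the foot b on the same side of the Pi-Ns line
    as the dentition (Ie), which in patient orientation is the solution with
    b anterior to Pi and inferior to Ns.  The side test is intrinsic to the
    landmarks, so the construction is invariant under rigid motions of the
    whole set.
    """
    if not landmarks.calibrated:
        raise ValueError("landmarks must be calibrated to mm first")
    anchor = landmarks.Pi
    v = landmarks.Ns - anchor
    L = float(np.linalg.norm(v))
    d = facebow.d_ns_mm
    if L < d:
        raise InfeasibleFacebowError(
            f"|Ns - anchor| = {L:.3f} mm < d_ns_mm = {d:.3f} mm: no tangent line"
        )
    if L == 0.0:
        raise InfeasibleFacebowError("Ns coincides with the Pi anchor")
    vhat = v / L
    theta = math.asin(min(d / L, 1.0))
    candidates = []
    for s in (+1.0, -1.0):
        c, sn = math.cos(s * theta), math.sin(s * theta)
        u = np.array([c * vhat[0] - sn * vhat[1], sn * vhat[0] + c * vhat[1]])
        b = anchor + math.sqrt(max(L * L - d * d, 0.0)) * u
        candidates.append(AOPLine(anchor=anchor, direction=u, b=b))
    # anatomic orientation: the foot on the dentition side of Pi-Ns
    side_ie = _cross2(v, landmarks.Ie - anchor)
    if side_ie != 0.0:
        for cand in candidates:
            if _cross2(v, cand.b - anchor) * side_ie > 0:
                return cand
    # degenerate (d_ns = 0 or Ie on the Pi-Ns line): fall back to the lower foot
    return min(candidates, key=lambda ln: ln.b[1])


def hinge_axis_position(aop: AOPLine, facebow: FacebowSpec) -> np.ndarray:
    """Place the arbitrary hinge axis Ax relative to the AOP anchor."""
    return (
        aop.anchor
        + facebow.ax_offset_along_mm * aop.direction
        + facebow.ax_offset_perp_mm * aop.normal
    )


def compute_mounting(landmarks: CephLandmarks, facebow: FacebowSpec) -> MountingValues:
    """Measure (alpha, AxV, AxH) from calibrated landmarks.

    The upper occlusal plane is the line Ie-Dc.  alpha is signed positive when
    the occlusal plane ascends posteriorly toward the AOP; AxV is the
    unsigned distance from Ax to its orthogonal projection Ax' on the
    occlusal plane, and AxH the distance from Ie to Ax'.
    """
    aop = construct_aop(landmarks, facebow)
    ax = hinge_axis_position(aop, facebow)
    e = landmarks.Dc - landmarks.Ie
    span = float(np.linalg.norm(e))
    if span == 0.0:
        raise ValueError("Ie and Dc coincide: occlusal plane undefined")
    # occlusal-plane direction expressed in the AOP frame (x anterior along AOP)
    dx = float(np.dot(e, aop.direction))
    dy = float(np.dot(e, aop.normal))
    alpha = math.degrees(math.atan2(dy, -dx))  # posterior ascent positive
    that = e / span
    rel = ax - landmarks.Ie
    along = float(np.dot(rel, that))
    ax_proj = landmarks.Ie + along * that
    axv = float(np.linalg.norm(ax - ax_proj))
    axh = abs(along)
    return MountingValues(alpha_deg=alpha, axv_mm=axv, axh_mm=axh)


@dataclass(frozen=True)
class LandmarkLayout:
    """Free degrees of freedom when synthesising a landmark set.

    ``ns_x_mm`` places the foot point b anterior of the Pi anchor;
    ``ie_dc_span_mm`` is the occlusal-plane span between Ie and Dc;
    ``ref_span_mm`` the distance between the scaling markers.  ``rotation_deg``
    and ``translation_mm`` apply a final rigid motion (mounting values are
    invariant under it).
    """

    ie_dc_span_mm: float = 40.0
    ns_x_mm: float = 80.0
    ref_span_mm: float = 50.0
    rotation_deg: float = 0.0
    translation_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.ie_dc_span_mm <= 0:
            raise ValueError("ie_dc_span_mm must be > 0")
        if self.ns_x_mm <= 0:
            raise ValueError("ns_x_mm must be > 0")
        if self.ref_span_mm <= 0:
            raise ValueError("ref_span_mm must be > 0")


def transform_landmarks(
    landmarks: CephLandmarks, rotation_deg: float, translation_mm=(0.0, 0.0)
) -> CephLandmarks:
    """Apply a rigid rotation+translation to every landmark."""
    r = math.radians(rotation_deg)
    R = np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])
    t = np.asarray(translation_mm, dtype=float)
    moved = {n: R @ p + t for n, p in landmarks.points().items()}
    return CephLandmarks(
        **moved,
        ref_distance_mm=landmarks.ref_distance_mm,
        calibrated=landmarks.calibrated,
    )


def invert_mounting(
    values: MountingValues,
    facebow: FacebowSpec,
    layout: LandmarkLayout = LandmarkLayout(),
) -> CephLandmarks:
    """Synthesise a calibrated landmark set realising a mounting triple.

    Construction (in the AOP frame, Pi anchor at the origin, AOP along +x):
    Ax sits at the facebow offsets; the occlusal plane is tilted by alpha and
    placed so that Ax projects onto it at distance AxV with the foot point
    AxH posterior of Ie.  :func:`compute_mounting` on the result reproduces
    the input triple.  Raises :class:`InfeasibleFacebowError` when the layout
    cannot realise the triple (e.g. Ie would fall posterior to the anchor
    region making b non-anterior).
    """
    a = math.radians(values.alpha_deg)
    p_post = np.array([-math.cos(a), math.sin(a)])  # posterior occlusal direction
    n_up = np.array([math.sin(a), math.cos(a)])  # occlusal normal, toward AOP
    ax = np.array([facebow.ax_offset_along_mm, facebow.ax_offset_perp_mm])
    ie = ax - values.axv_mm * n_up - values.axh_mm * p_post
    if ie[1] >= -1e-9:
        # alpha at or above the Balkwill angle would lift the incisor edge to
        # the axis-orbital plane, outside the anatomic configuration
        raise InfeasibleFacebowError(
            f"triple {values.as_tuple()}: incisor edge would not lie below the AOP"
        )
    dc = ie + layout.ie_dc_span_mm * p_post
    ns = np.array([layout.ns_x_mm, facebow.d_ns_mm])
    ref0 = np.array([0.0, -30.0])
    ref1 = np.array([0.0, -30.0 - layout.ref_span_mm])
    lm = CephLandmarks(
        Pi=np.zeros(2),
        Ns=ns,
        Ie=ie,
        Dc=dc,
        Ref0=ref0,
        Ref1=ref1,
        ref_distance_mm=layout.ref_span_mm,
        calibrated=True,
    )
    if layout.rotation_deg or any(layout.translation_mm):
        lm = transform_landmarks(lm, layout.rotation_deg, layout.translation_mm)
    # feasibility: the construction must round-trip
    check = compute_mounting(lm, facebow)
    if (
        abs(check.alpha_deg - values.alpha_deg) > 1e-6
        or abs(check.axv_mm - values.axv_mm) > 1e-6
        or abs(check.axh_mm - values.axh_mm) > 1e-6
    ):
        raise InfeasibleFacebowError(
            f"triple {values.as_tuple()} infeasible under facebow {facebow}"
        )
    return lm


def decalibrate(landmarks: CephLandmarks, px_per_mm: float) -> CephLandmarks:
    """Express a calibrated landmark set in raw pixels at a given spacing."""
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be > 0")
    raw = {n: p * px_per_mm for n, p in landmarks.points().items()}
    return CephLandmarks(
        **raw, ref_distance_mm=landmarks.ref_distance_mm, calibrated=False
    )


def derive_articulator_values(values: MountingValues) -> DerivedArticulatorValues:
    """Bonwill-arm and Balkwill-angle equivalents.

    Ax, Ie and the foot point Ax' form a right triangle with the right angle
    at Ax', so Ie-Ax = sqrt(AxH^2 + AxV^2) and the Balkwill angle (occlusal
    plane vs. the segment Ie-Ax) is atan(AxV / AxH).
    """
    if values.axh_mm == 0:
        raise ValueError("Balkwill angle undefined for AxH = 0")
    ie_ax = math.hypot(values.axh_mm, values.axv_mm)
    balkwill = math.degrees(math.atan2(values.axv_mm, values.axh_mm))
    return DerivedArticulatorValues(ie_ax_mm=ie_ax, balkwill_deg=balkwill)


def round_half_up(x: float) -> int:
    """Commercial rounding to the nearest integer; ties go away from zero."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def round_presets(
    cluster_means: dict[str, MountingValues],
) -> dict[str, tuple[int, int, int]]:
    """Round per-phenotype mean triples to integer mounting presets."""
    return {
        label: (
            round_half_up(v.alpha_deg),
            round_half_up(v.axv_mm),
            round_half_up(v.axh_mm),
        )
        for label, v in cluster_means.items()
    }
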