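"""Rigid mounting of an intraoral scan against the virtual hinge axis.

Given a mounting triple (alpha, AxV, AxH), build the 3D scene that places a
maxillary scan in virtual-articulator space.  The scan is assumed
pre-oriented: upper occlusal plane on the ground plane (z = 0), midsagittal
plane x = 0, upper incisor edge Ie at the origin, anterior = +y,
superior = +z, patient-left = +x.

Procedure: the hinge axis starts as the transverse line through
(0, -AxH, +AxV) — shifted posteriorly along the midline by AxH and
superiorly by AxV — then the whole scene (scan and axis) is rotated by alpha
about the transverse axis through Ie, the posterior side moving superiorly.
Ie stays on the ground plane throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import MountingValues

__all__ = ["MountingScene", "build_mounting_transform", "apply_transform"]


@dataclass(frozen=True)
class MountingScene:
    """A mounted scene: composite transform, hinge axis, and references."""

    transform: np.ndarray  # 4x4 homogeneous rigid matrix, row-major
    hinge_axis_point: np.ndarray  # 3D point on the hinge axis, mm
    hinge_axis_direction: np.ndarray  # transverse unit vector
    ie_position: np.ndarray  # 3D point, fixed center of rotation
    ground_plane_point: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )
    ground_plane_normal: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )


def _rot_x(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def build_mounting_transform(
    values: MountingValues, posterior_rotates_superiorly: bool = True
) -> MountingScene:
    """Build the mounting transform and hinge-axis line for a triple.

    The rotation sense is chosen so the posterior end of the scan moves
    superiorly (occlusal plane and AOP converge posteriorly); pass
    ``posterior_rotates_superiorly=False`` to flip it.
    """
    alpha = math.radians(values.alpha_deg)
    theta = -alpha if posterior_rotates_superiorly else alpha
    R = _rot_x(theta)
    T = np.eye(4)
    T[:3, :3] = R
    axis_point0 = np.array([0.0, -values.axh_mm, values.axv_mm])
    return MountingScene(
        transform=T,
        hinge_axis_point=R @ axis_point0,
        hinge_axis_direction=np.array([1.0, 0.0, 0.0]),
        ie_position=np.zeros(3),
    )


def apply_transform(scene: MountingScene, points) -> np.ndarray:
    """Apply the scene transform to an (N, 3) array of points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates")
    hom = np.hstack([pts, np.ones((pts.shape[0], 1))])
    return (scene.transform @ hom.T).T[:, :3]
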