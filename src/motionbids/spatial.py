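"""Rotation-representation conversions and spatial-axes remapping.

Orientations may be shared either as Euler angles — a sequence of
*extrinsic* elemental rotations about three distinct fixed axes (Tait-Bryan
sequences XYZ, XZY, YXZ, YZX, ZXY, ZYX) — or as unit quaternions with
components quat_x/quat_y/quat_z and the non-axial quat_w.  The RotationRule
("left-hand"/"right-hand") fixes which angular direction counts as positive
about an axis; under the left-hand rule all angles are sign-flipped before
composition.

Quaternions are stored scalar-first (w, x, y, z) internally, Hamilton
convention, and mapped to the quat_* channel labels on I/O.  The
handedness rule is applied only to the Euler-angle interpretation;
quaternion channels are assumed right-hand Hamilton throughout.

Axis conventions (the SpatialAxes string, e.g. "ARI" for X-anterior,
Y-right, Z-inferior) are remapped with exact signed permutation matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .model import ModelError, ROTATION_ORDERS, ROTATION_RULES, ReferenceFrame

__all__ = [
    "SpatialError",
    "euler_to_matrix",
    "euler_to_quat",
    "quat_to_matrix",
    "quat_to_euler",
    "normalize_quat",
    "AxisMap",
    "axis_map",
    "remap_orientation",
]


class SpatialError(ValueError):
    """Invalid rotation or axis-convention input."""


def _check_order_rule(order: str, rule: str) -> None:
    if order not in ROTATION_ORDERS:
        raise SpatialError(f"rotation order must be one of {ROTATION_ORDERS}, got {order!r}")
    if rule not in ROTATION_RULES:
        raise SpatialError(f"rotation rule must be one of {ROTATION_RULES}, got {rule!r}")


def _signed_angles(angles, rule: str, degrees: bool) -> np.ndarray:
    angles = np.asarray(angles, dtype=float)
    if not np.all(np.isfinite(angles)):
        raise SpatialError("angles must be finite")
    if degrees:
        angles = np.deg2rad(angles)
    if rule == "left-hand":
        angles = -angles
    return angles


def euler_to_matrix(angles, order: str, rule: str = "right-hand",
                    degrees: bool = False) -> np.ndarray:
    """Rotation matrix of an extrinsic Euler triple.

    For order "PQR" the matrix is R_R(θ3)·R_Q(θ2)·R_P(θ1) with right-hand
    elemental rotations; the left-hand rule negates all angles first.
    ``angles`` may be shape (3,) or (n, 3).
    """
    _check_order_rule(order, rule)
    signed = _signed_angles(angles, rule, degrees)
    # lowercase axis sequence = extrinsic composition in scipy
    return Rotation.from_euler(order.lower(), signed).as_matrix()


def normalize_quat(q) -> np.ndarray:
    """Normalize (…, 4) scalar-first quaternions to unit norm with the
    canonical sign w ≥ 0 (q and −q denote the same rotation)."""
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0) or not np.all(np.isfinite(norm)):
        raise SpatialError("cannot normalize a zero-norm or non-finite quaternion")
    q = q / norm
    flip = np.where(q[..., :1] < 0, -1.0, 1.0)
    return q * flip


def _rotation_from_quat_wxyz(q) -> Rotation:
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(np.concatenate([q[..., 1:], q[..., :1]], axis=-1))


def _quat_wxyz_from_rotation(rot: Rotation) -> np.ndarray:
    xyzw = rot.as_quat()
    wxyz = np.concatenate([xyzw[..., 3:], xyzw[..., :3]], axis=-1)
    return normalize_quat(wxyz)


def euler_to_quat(angles, order: str, rule: str = "right-hand",
                  degrees: bool = False) -> np.ndarray:
    """Scalar-first unit quaternion (w ≥ 0) of an extrinsic Euler triple."""
    _check_order_rule(order, rule)
    signed = _signed_angles(angles, rule, degrees)
    return _quat_wxyz_from_rotation(Rotation.from_euler(order.lower(), signed))


def quat_to_matrix(q) -> np.ndarray:
    """Rotation matrix of a scalar-first quaternion (normalized first)."""
    return _rotation_from_quat_wxyz(normalize_quat(q)).as_matrix()


def quat_to_euler(q, order: str, rule: str = "right-hand",
                  degrees: bool = False):
    """Extrinsic Euler angles of a quaternion: returns ``(angles,
    gimbal_lock)``.

    At gimbal lock (middle angle at ±90°) one rotational degree of freedom
    is lost: the third angle is set to 0, the remaining freedom is folded
    into the first angle, and the ``gimbal_lock`` flag is set.
    """
    _check_order_rule(order, rule)
    rot = _rotation_from_quat_wxyz(normalize_quat(q))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        angles = rot.as_euler(order.lower())
    locked = any("Gimbal lock" in str(w.message) for w in caught)
    if rule == "left-hand":
        angles = -angles
    if degrees:
        angles = np.rad2deg(angles)
    return angles, locked


# ---------------------------------------------------------------------------
# SpatialAxes remapping
# ---------------------------------------------------------------------------

# letter -> (anatomical dimension index, sign); A/R/S are the positive ends
_LETTER_DIM = {
    "A": (0, +1.0), "P": (0, -1.0),
    "R": (1, +1.0), "L": (1, -1.0),
    "S": (2, +1.0), "I": (2, -1.0),
}


def _parse_axes(axes: str):
    """SpatialAxes string -> list of (dim, sign) or None per X/Y/Z slot."""
    try:
        ReferenceFrame.check_spatial_axes(axes)
    except ModelError as exc:
        raise SpatialError(str(exc)) from exc
    return [None if c == "_" else _LETTER_DIM[c] for c in axes]


@dataclass(frozen=True)
class AxisMap:
    """Signed-permutation change of basis between two SpatialAxes
    conventions.  For a position ``p`` in source axes, ``matrix @ p`` is
    the same point in target axes.  Rows for unused target axes are zero
    and listed in ``unused_target_axes``."""

    matrix: np.ndarray
    source: str
    target: str
    unused_target_axes: tuple = ()

    @property
    def is_full_3d(self) -> bool:
        return not self.unused_target_axes and "_" not in self.source

    @property
    def determinant(self) -> float:
        return float(round(np.linalg.det(self.matrix)))

    def apply(self, vectors) -> np.ndarray:
        """Map (..., 3) position-like vectors from source to target axes."""
        vectors = np.asarray(vectors, dtype=float)
        return vectors @ self.matrix.T

    def inverse(self) -> "AxisMap":
        if not self.is_full_3d:
            raise SpatialError("only full-3D axis maps are invertible")
        return AxisMap(matrix=self.matrix.T, source=self.target, target=self.source)


def axis_map(source: str, target: str) -> AxisMap:
    """Build the signed permutation mapping coordinates from one
    SpatialAxes convention to another, e.g. "ALS" → "ARI" maps
    (1, 2, 3) to (1, −2, −3).

    Every anatomical dimension used by the target must be present in the
    source; otherwise the dimension is unmappable and an error is raised.
    """
    src = _parse_axes(source)
    tgt = _parse_axes(target)
    matrix = np.zeros((3, 3))
    unused = []
    src_by_dim = {dim: (j, sign) for j, ds in enumerate(src) if ds for dim, sign in [ds]}
    for i, ds in enumerate(tgt):
        if ds is None:
            unused.append("XYZ"[i])
            continue
        dim, sign = ds
        if dim not in src_by_dim:
            raise SpatialError(
                f"target axis {'XYZ'[i]}={target[i]} uses an anatomical dimension "
                f"absent from source {source!r}"
            )
        j, src_sign = src_by_dim[dim]
        matrix[i, j] = sign * src_sign
    return AxisMap(matrix=matrix, source=source, target=target,
                   unused_target_axes=tuple(unused))


def remap_tracking_system(system, target_axes: str):
    """Re-express every position-like and orientation channel of a tracking
    system in a new SpatialAxes convention, in place.

    Channels are grouped per (tracked point, reference frame); groups whose
    reference frame declares a full-3D ``SpatialAxes`` are transformed with
    the signed permutation into ``target_axes``.  Euler orientation triples
    go through quaternion conjugation and back using the frame's declared
    RotationOrder/RotationRule; when the permutation is improper
    (det = −1) the frame's RotationRule is toggled.  The reference-frame
    descriptions are updated to the new axes string.  Returns the labels of
    the frames that were remapped.
    """
    from .model import ChannelType, Component  # late import keeps module deps one-way

    vector_types = {ChannelType.POS, ChannelType.VEL, ChannelType.ACCEL,
                    ChannelType.GYRO, ChannelType.ANGACC, ChannelType.MAGN}
    axis_components = {Component.x: 0, Component.y: 1, Component.z: 2}
    remapped = []
    for label, frame in system.reference_frames.items():
        if frame.spatial_axes is None or "_" in frame.spatial_axes:
            continue
        amap = axis_map(frame.spatial_axes, target_axes)
        flip = amap.determinant < 0

        groups: dict = {}
        for j, c in enumerate(system.channels):
            if c.reference_frame != label:
                continue
            groups.setdefault((c.tracked_point, c.type), {})[c.component] = j

        for (point, ctype), comps in groups.items():
            if ctype in vector_types and set(comps) == set(axis_components):
                cols = [comps[Component.x], comps[Component.y], comps[Component.z]]
                system.samples[:, cols] = amap.apply(system.samples[:, cols])
            elif ctype is ChannelType.ORNT and set(comps) >= set(axis_components):
                cols = [comps[Component.x], comps[Component.y], comps[Component.z]]
                order = frame.rotation_order or "XYZ"
                rule = frame.rotation_rule or "right-hand"
                degrees = all(
                    system.channels[j].units == "deg" for j in cols)
                # angle-about-axis storage -> sequence order for conversion
                seq_cols = [cols["XYZ".index(a)] for a in order]
                angles = system.samples[:, seq_cols]
                q = euler_to_quat(angles, order=order, rule=rule, degrees=degrees)
                q_new, _ = remap_orientation(q, amap)
                new_rule = _toggled_rule(rule) if flip else rule
                new_angles, _ = quat_to_euler(q_new, order=order, rule=new_rule,
                                              degrees=degrees)
                system.samples[:, seq_cols] = new_angles
            elif ctype is ChannelType.ORNT:
                quat_order = (Component.quat_w, Component.quat_x,
                              Component.quat_y, Component.quat_z)
                if set(comps) >= set(quat_order):
                    cols = [comps[c] for c in quat_order]
                    q_new, _ = remap_orientation(system.samples[:, cols], amap)
                    system.samples[:, cols] = q_new

        frame.spatial_axes = target_axes
        if flip and frame.rotation_rule is not None:
            frame.rotation_rule = _toggled_rule(frame.rotation_rule)
        remapped.append(label)
    return remapped


def _toggled_rule(rule: str) -> str:
    return "left-hand" if rule == "right-hand" else "right-hand"


def remap_orientation(q, amap: AxisMap):
    """Re-express an orientation quaternion under a change of spatial axes.

    Returns ``(q', handedness_flipped)`` where the matrix of ``q'`` equals
    M·R(q)·Mᵀ.  When det(M) = −1 the conjugated matrix is still a proper
    rotation, but the sense of positive rotation about every axis flips, so
    the reference frame's RotationRule must be toggled between left-hand
    and right-hand — reported through the flag.
    """
    if not amap.is_full_3d:
        raise SpatialError("orientation remapping requires full 3-axis source and target")
    det = amap.determinant
    rotmat = quat_to_matrix(q)
    conjugated = np.einsum("ij,...jk,lk->...il", amap.matrix, rotmat, amap.matrix)
    q_new = _quat_wxyz_from_rotation(Rotation.from_matrix(conjugated))
    return q_new, det < 0
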