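"""Forward/inverse kinematics of a 4-DOF shoulder–elbow arm and marker velocities.

The arm model has four rotational degrees of freedom: shoulder
abduction/adduction (q1), shoulder flexion/extension (q2), shoulder
external/internal rotation (q3) and elbow flexion/extension (q4).  The
world frame is x lateral (toward the subject's left), y anterior, z
superior.  In the zero posture (q1 = q2 = q3 = 0, q4 = pi) the arm hangs
straight down along -z with the palm facing anterior (+y); decreasing q4
from pi flexes the elbow so the forearm swings toward +y.

The shoulder rotation is composed as ``R(q1, q2, q3) = Ry(q1) Rx(q2) Rz(q3)``.
Because the upper-arm rest axis is -z, Rz(q3) leaves the elbow position
invariant and q3 acts only on the forearm — matching the anatomical
reading of "external/internal rotation".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "ArmGeometry",
    "JointAngleSeries",
    "forward_kinematics",
    "inverse_kinematics",
    "tangential_velocity",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArmGeometry:
    """Segment lengths in meters: shoulder–elbow and elbow–wrist."""

    upper: float = 0.30
    fore: float = 0.25

    def __post_init__(self) -> None:
        if self.upper <= 0 or self.fore <= 0:
            raise ValueError("segment lengths must be positive")


@dataclass
class JointAngleSeries:
    """Time series of the four joint angles, radians, sampled at ``fs`` Hz.

    Each of q1..q4 is a 1-D array of equal length.  q4 lives in (0, pi]
    (pi = full elbow extension); q2 in [-pi/2, pi/2]; q1, q3 in (-pi, pi].
    """

    q1: np.ndarray
    q2: np.ndarray
    q3: np.ndarray
    q4: np.ndarray
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.q1, self.q2, self.q3, self.q4 = (
            np.atleast_1d(np.asarray(q, dtype=float))
            for q in (self.q1, self.q2, self.q3, self.q4)
        )
        n = {len(q) for q in (self.q1, self.q2, self.q3, self.q4)}
        if len(n) != 1:
            raise ValueError("q1..q4 must have equal length")

    def __len__(self) -> int:
        return len(self.q1)

    def as_array(self) -> np.ndarray:
        """Stack to shape (n, 4), columns q1..q4."""
        return np.column_stack([self.q1, self.q2, self.q3, self.q4])


def _rx(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    z, o = np.zeros_like(c), np.ones_like(c)
    return np.stack(
        [np.stack([o, z, z], -1), np.stack([z, c, -s], -1), np.stack([z, s, c], -1)], -2
    )


def _ry(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    z, o = np.zeros_like(c), np.ones_like(c)
    return np.stack(
        [np.stack([c, z, s], -1), np.stack([z, o, z], -1), np.stack([-s, z, c], -1)], -2
    )


def _rz(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    z, o = np.zeros_like(c), np.ones_like(c)
    return np.stack(
        [np.stack([c, -s, z], -1), np.stack([s, c, z], -1), np.stack([z, z, o], -1)], -2
    )


def shoulder_rotation(q1: np.ndarray, q2: np.ndarray, q3: np.ndarray) -> np.ndarray:
    """Rotation matrices R = Ry(q1) @ Rx(q2) @ Rz(q3), shape (..., 3, 3)."""
    return _ry(np.asarray(q1, float)) @ _rx(np.asarray(q2, float)) @ _rz(np.asarray(q3, float))


def forward_kinematics(
    q: JointAngleSeries,
    geom: ArmGeometry,
    shoulder: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Map joint angles to elbow and wrist positions.

    Parameters
    ----------
    q : JointAngleSeries
    geom : ArmGeometry
    shoulder : (n, 3) array or None
        Shoulder marker positions; origin if None.

    Returns
    -------
    elbow, wrist : (n, 3) arrays, meters.
    """
    n = len(q)
    if shoulder is None:
        shoulder = np.zeros((n, 3))
    shoulder = np.broadcast_to(np.asarray(shoulder, float), (n, 3))
    if not np.all(np.isfinite(q.as_array())):
        raise ValueError("joint angles must be finite")
    if np.any(q.q4 <= 0) or np.any(q.q4 > np.pi + 1e-12):
        raise ValueError("q4 must lie in (0, pi]")

    R = shoulder_rotation(q.q1, q.q2, q.q3)
    upper_dir = np.array([0.0, 0.0, -1.0])
    elbow = shoulder + geom.upper * (R @ upper_dir)
    # Forearm direction in the upper-arm frame; q4 = pi is full extension.
    a = np.pi - q.q4
    fore_local = np.stack([np.zeros_like(a), np.sin(a), -np.cos(a)], -1)
    wrist = elbow + geom.fore * np.einsum("...ij,...j->...i", R, fore_local)
    return elbow, wrist


def inverse_kinematics(
    shoulder: np.ndarray,
    elbow: np.ndarray,
    wrist: np.ndarray,
    geom: ArmGeometry,
    length_tolerance: float = 0.05,
    singular_threshold: float = 1e-7,
    fs: float = 100.0,
) -> JointAngleSeries:
    """Recover joint angles from shoulder/elbow/wrist marker positions.

    Segment lengths are validated against ``geom`` within a relative
    ``length_tolerance`` (default 5%).  At the elbow-extension singularity
    (q4 -> pi) the shoulder rotation q3 is indeterminate from three markers;
    the last well-defined value is carried forward (0 at series start), and
    a warning is logged.
    """
    shoulder, elbow, wrist = (
        np.atleast_2d(np.asarray(p, float)) for p in (shoulder, elbow, wrist)
    )
    u_vec = elbow - shoulder
    f_vec = wrist - elbow
    lu = np.linalg.norm(u_vec, axis=-1)
    lf = np.linalg.norm(f_vec, axis=-1)
    bad = (np.abs(lu - geom.upper) > length_tolerance * geom.upper) | (
        np.abs(lf - geom.fore) > length_tolerance * geom.fore
    )
    if np.any(bad):
        idx = np.flatnonzero(bad)
        raise ValueError(
            f"segment lengths violate geometry beyond {length_tolerance:.0%} "
            f"at {idx.size} samples (first few: {idx[:10].tolist()})"
        )

    u = u_vec / lu[:, None]
    cos_q4 = np.einsum("ij,ij->i", -u_vec, f_vec) / (lu * lf)
    q4 = np.arccos(np.clip(cos_q4, -1.0, 1.0))

    q2 = np.arcsin(np.clip(u[:, 1], -1.0, 1.0))
    q1 = np.arctan2(-u[:, 0], -u[:, 2])

    # Forearm direction in the shoulder-rotated frame (undo Ry(q1) Rx(q2)):
    # g = Rz(q3) @ (0, sin(pi - q4), -cos(pi - q4)).
    R12 = _ry(q1) @ _rx(q2)
    g = np.einsum("...ji,...j->...i", R12, f_vec / lf[:, None])  # R^T f
    sin_a = np.sin(np.pi - q4)
    q3 = np.full(len(q4), np.nan)
    ok = sin_a > singular_threshold
    q3[ok] = np.arctan2(-g[ok, 0], g[ok, 1])
    if not np.all(ok):
        log.warning(
            "q3 indeterminate at %d near-extension samples; carrying forward",
            int(np.sum(~ok)),
        )
        last = 0.0
        for i in range(len(q3)):
            if np.isnan(q3[i]):
                q3[i] = last
            else:
                last = q3[i]
    return JointAngleSeries(q1=q1, q2=q2, q3=q3, q4=q4, fs=fs)


def tangential_velocity(
    position: np.ndarray,
    fs: float,
    smooth_cutoff: float | None = 5.0,
    smooth_order: int = 2,
) -> np.ndarray:
    """Speed (m/s) of a 3D marker: central-difference velocity norm, smoothed.

    The derivative is a central difference per axis (one-sided at the ends),
    followed by the Euclidean norm and a causal Butterworth low-pass at
    ``smooth_cutoff`` Hz (None disables smoothing).  Raw differentiation of
    100 Hz optical markers amplifies noise, hence the default 5 Hz cutoff,
    well above reach dynamics.
    """
    position = np.atleast_2d(np.asarray(position, float))
    if position.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    vel = np.gradient(position, axis=0) * fs
    speed = np.linalg.norm(vel, axis=-1)
    if smooth_cutoff is not None:
        sos = sps.butter(smooth_order, smooth_cutoff, btype="low", fs=fs, output="sos")
        # Initialize at the first value's step response to avoid a start-up dip.
        zi = sps.sosfilt_zi(sos) * speed[0]
        speed, _ = sps.sosfilt(sos, speed, zi=zi)
        speed = np.clip(speed, 0.0, None)  # filter undershoot is not motion
    return speed
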