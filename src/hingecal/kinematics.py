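"""Hinge-joint constraint mathematics.

A 1-DOF (hinge) joint constrains the motion of the two segments it connects:
both segments may only rotate independently about a single axis.  With one IMU
rigidly attached to each segment, that axis is described by two constant unit
vectors ``j1`` and ``j2``, one in each sensor frame.  Two scalar constraints
follow from rigid-body kinematics and hold at every sample of an arbitrary
motion:

* gyroscope constraint: ``||w1 x j1|| - ||w2 x j2|| = 0`` — the angular-rate
  components perpendicular to the hinge axis have equal magnitude in both
  frames;
* accelerometer constraint (approximate): ``j1^T a1 - j2^T a2 ~ 0`` — the
  projections of the measured accelerations onto the axis agree whenever the
  rotational acceleration components along the axis are small.

This module provides the spherical parametrization of the axis pair, the
weighted residuals built from the two constraints, the summed-squares cost,
and its analytic Jacobian, which the Gauss-Newton solver in
:mod:`hingecal.estimate` consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AxisParams",
    "ResidualWeights",
    "SampleBatch",
    "spherical_to_axis",
    "axis_to_spherical",
    "rotation_operator_K",
    "gyro_residual",
    "accel_residual",
    "residual_vector",
    "cost",
    "residual_jacobian",
    "angular_deviation",
]


# --------------------------------------------------------------------------
# parametrization
# --------------------------------------------------------------------------

def spherical_to_axis(theta, phi):
    """Map inclination/azimuth angles to a unit vector.

    ``j(theta, phi) = (cos(theta) cos(phi), cos(theta) sin(phi), sin(theta))``

    Accepts scalars or broadcastable arrays; the last axis of the result holds
    the three components.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    ct = np.cos(theta)
    return np.stack([ct * np.cos(phi), ct * np.sin(phi), np.sin(theta)], axis=-1)


def axis_to_spherical(j) -> tuple[float, float]:
    """Inverse of :func:`spherical_to_axis` for a unit vector.

    Returns ``(theta, phi)`` with ``theta`` in ``[-pi/2, pi/2]`` and ``phi``
    in ``(-pi, pi]``.  At the poles (``|cos(theta)| < 1e-12``) the azimuth is
    undefined and returned as 0 by convention.
    """
    j = np.asarray(j, dtype=float)
    theta = float(np.arcsin(np.clip(j[2], -1.0, 1.0)))
    if math.cos(theta) < 1e-12:
        phi = 0.0
    else:
        phi = float(np.arctan2(j[1], j[0]))
        if phi <= -math.pi:
            phi = math.pi
    return theta, phi


@dataclass(frozen=True)
class AxisParams:
    """The 4-vector ``x = (theta1, phi1, theta2, phi2)`` of spherical
    coordinates encoding the hinge axis in both sensor frames."""

    theta1: float
    phi1: float
    theta2: float
    phi2: float

    @classmethod
    def from_array(cls, x) -> "AxisParams":
        x = np.asarray(x, dtype=float).reshape(4)
        return cls(float(x[0]), float(x[1]), float(x[2]), float(x[3]))

    @classmethod
    def from_axes(cls, j1, j2) -> "AxisParams":
        return cls(*axis_to_spherical(j1), *axis_to_spherical(j2))

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.phi1, self.theta2, self.phi2])

    def axis1(self) -> np.ndarray:
        return spherical_to_axis(self.theta1, self.phi1)

    def axis2(self) -> np.ndarray:
        return spherical_to_axis(self.theta2, self.phi2)

    def flipped(self) -> "AxisParams":
        """The parameter vector mapping to ``(j1, -j2)``.

        ``(theta1, phi1, theta2, phi2) -> (theta1, phi1, -theta2, phi2 + pi)``
        negates the second axis and leaves the first unchanged; it is the
        reinitialization used to probe the opposite sign pairing.
        """
        return AxisParams(self.theta1, self.phi1, -self.theta2, self.phi2 + math.pi)

    def normalized(self) -> "AxisParams":
        """Wrap angles to the canonical ranges (reporting only; the cost is
        periodic so wrapping never changes it)."""
        return AxisParams.from_axes(self.axis1(), self.axis2())


def _as_params_array(x) -> np.ndarray:
    if isinstance(x, AxisParams):
        return x.as_array()
    return np.asarray(x, dtype=float).reshape(4)


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidualWeights:
    """Relative weighting of the gyroscope and accelerometer residuals.

    The single tuning knob is the ratio ``w0 = w_omega / w_a``; the
    convention ``w_omega = sqrt(w0)``, ``w_a = 1/sqrt(w0)`` fixes the overall
    scale.  ``w0`` defaults to 50, which sits inside the broad insensitive
    range (roughly 1e1..1e5) where both constraints contribute.
    """

    w_omega: float
    w_a: float

    def __post_init__(self):
        if not (self.w_omega > 0 and self.w_a > 0):
            raise ValueError("residual weights must be strictly positive")

    @classmethod
    def from_w0(cls, w0: float = 50.0) -> "ResidualWeights":
        if not w0 > 0:
            raise ValueError("w0 must be strictly positive")
        return cls(math.sqrt(w0), 1.0 / math.sqrt(w0))

    @property
    def w0(self) -> float:
        return self.w_omega / self.w_a


class SampleBatch:
    """Paired, time-aligned gyroscope/accelerometer streams from two IMUs.

    All channel arrays share one length ``N >= 1`` and ``times`` is strictly
    increasing.  Gyroscope units rad/s, accelerometer units m/s^2.
    """

    __slots__ = ("times", "gyro1", "gyro2", "accel1", "accel2")

    def __init__(self, times, gyro1, gyro2, accel1, accel2):
        self.times = np.asarray(times, dtype=float).reshape(-1)
        self.gyro1 = np.asarray(gyro1, dtype=float).reshape(-1, 3)
        self.gyro2 = np.asarray(gyro2, dtype=float).reshape(-1, 3)
        self.accel1 = np.asarray(accel1, dtype=float).reshape(-1, 3)
        self.accel2 = np.asarray(accel2, dtype=float).reshape(-1, 3)
        n = len(self.times)
        for arr in (self.gyro1, self.gyro2, self.accel1, self.accel2):
            if len(arr) != n:
                raise ValueError("all channel arrays must share one length")
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def slice(self, start: int, stop: int | None = None) -> "SampleBatch":
        sl = slice(start, stop)
        return SampleBatch(self.times[sl], self.gyro1[sl], self.gyro2[sl],
                           self.accel1[sl], self.accel2[sl])

    def take(self, gyro_idx, accel_idx) -> "SelectedData":
        """Sub-sample the two channels independently (used after sample
        selection, where the retained gyro and accel index sets differ)."""
        gyro_idx = np.asarray(gyro_idx, dtype=int)
        accel_idx = np.asarray(accel_idx, dtype=int)
        return SelectedData(self.gyro1[gyro_idx], self.gyro2[gyro_idx],
                            self.accel1[accel_idx], self.accel2[accel_idx])

    @classmethod
    def concatenate(cls, batches) -> "SampleBatch":
        batches = list(batches)
        return cls(np.concatenate([b.times for b in batches]),
                   np.concatenate([b.gyro1 for b in batches]),
                   np.concatenate([b.gyro2 for b in batches]),
                   np.concatenate([b.accel1 for b in batches]),
                   np.concatenate([b.accel2 for b in batches]))


@dataclass(frozen=True)
class SelectedData:
    """Measurement set where the gyro and accel channels may hold different
    (independently selected) samples."""

    gyro1: np.ndarray
    gyro2: np.ndarray
    accel1: np.ndarray
    accel2: np.ndarray


# --------------------------------------------------------------------------
# rigid-body operator
# --------------------------------------------------------------------------

def rotation_operator_K(omega, omega_dot) -> np.ndarray:
    """Matrix form of the rotational acceleration operator.

    ``K(w, wd) r = w x (w x r) + wd x r`` collects the centripetal and
    tangential acceleration of a point at constant body-frame offset ``r``
    from the rotation centre.  Accepts single triplets or ``(N, 3)`` stacks;
    returns ``(3, 3)`` or ``(N, 3, 3)``.
    """
    w = np.asarray(omega, dtype=float)
    wd = np.asarray(omega_dot, dtype=float)
    w, wd = np.broadcast_arrays(w, wd)
    single = w.ndim == 1
    w = np.atleast_2d(w)
    wd = np.atleast_2d(wd)
    wx, wy, wz = w[:, 0], w[:, 1], w[:, 2]
    dx, dy, dz = wd[:, 0], wd[:, 1], wd[:, 2]
    K = np.empty(w.shape[:1] + (3, 3))
    K[:, 0, 0] = -wy**2 - wz**2
    K[:, 0, 1] = wx * wy - dz
    K[:, 0, 2] = wx * wz + dy
    K[:, 1, 0] = wx * wy + dz
    K[:, 1, 1] = -wx**2 - wz**2
    K[:, 1, 2] = wy * wz - dx
    K[:, 2, 0] = wx * wz - dy
    K[:, 2, 1] = wy * wz + dx
    K[:, 2, 2] = -wx**2 - wy**2
    return K[0] if single else K


# --------------------------------------------------------------------------
# residuals, cost, Jacobian
# --------------------------------------------------------------------------

def gyro_residual(x, gyro1, gyro2, w: ResidualWeights):
    """Weighted gyroscope-constraint residual.

    ``e_w = w_omega * (||y_w1 x j1|| - ||y_w2 x j2||)``.  Works on single
    samples ``(3,)`` or batches ``(N, 3)``.
    """
    xa = _as_params_array(x)
    j1 = spherical_to_axis(xa[0], xa[1])
    j2 = spherical_to_axis(xa[2], xa[3])
    n1 = np.linalg.norm(np.cross(np.asarray(gyro1, dtype=float), j1), axis=-1)
    n2 = np.linalg.norm(np.cross(np.asarray(gyro2, dtype=float), j2), axis=-1)
    return w.w_omega * (n1 - n2)


def accel_residual(x, accel1, accel2, w: ResidualWeights):
    """Weighted accelerometer-constraint residual.

    ``e_a = w_a * (j1^T y_a1 - j2^T y_a2)``.  Works on single samples or
    batches.
    """
    xa = _as_params_array(x)
    j1 = spherical_to_axis(xa[0], xa[1])
    j2 = spherical_to_axis(xa[2], xa[3])
    return w.w_a * (np.asarray(accel1, dtype=float) @ j1
                    - np.asarray(accel2, dtype=float) @ j2)


def residual_vector(x, data, w: ResidualWeights) -> np.ndarray:
    """Stacked residual vector: all gyro residuals first, then all accel
    residuals.  ``data`` is any object with gyro1/gyro2/accel1/accel2
    attributes (the two channel pairs may have different lengths)."""
    ew = gyro_residual(x, data.gyro1, data.gyro2, w)
    ea = accel_residual(x, data.accel1, data.accel2, w)
    return np.concatenate([np.atleast_1d(ew), np.atleast_1d(ea)])


def cost(x, data, w: ResidualWeights) -> float:
    """Sum of squared residuals ``V(x)`` over the batch."""
    e = residual_vector(x, data, w)
    return float(e @ e)


def _axis_jacobian(theta: float, phi: float) -> np.ndarray:
    """``d j / d (theta, phi)`` as a (3, 2) matrix."""
    st, ct = math.sin(theta), math.cos(theta)
    sp, cp = math.sin(phi), math.cos(phi)
    return np.array([[-st * cp, -ct * sp],
                     [-st * sp, ct * cp],
                     [ct, 0.0]])


def _cross_norm_grad(y: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Per-sample gradient of ``||y x j||`` w.r.t. ``j``: ``((y x j) x y) /
    ||y x j||``, with the singular samples (``||y x j|| = 0``) set to the
    zero subgradient so stationary data cannot inject NaNs."""
    c = np.cross(y, j)
    n = np.linalg.norm(c, axis=-1)
    g = np.cross(c, y)
    nz = n > 0.0
    g[nz] /= n[nz, None]
    g[~nz] = 0.0
    return g


def residual_jacobian(x, data, w: ResidualWeights) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Jacobian of the stacked residuals.

    Returns ``(J, e)`` where ``J`` is ``(Ng + Na) x 4`` with the row ordering
    of :func:`residual_vector` (gyro rows then accel rows) and the column
    ordering ``(theta1, phi1, theta2, phi2)``, and ``e`` is the residual
    vector at ``x``.
    """
    xa = _as_params_array(x)
    j1 = spherical_to_axis(xa[0], xa[1])
    j2 = spherical_to_axis(xa[2], xa[3])
    D1 = _axis_jacobian(xa[0], xa[1])  # (3, 2)
    D2 = _axis_jacobian(xa[2], xa[3])

    g1 = np.atleast_2d(np.asarray(data.gyro1, dtype=float))
    g2 = np.atleast_2d(np.asarray(data.gyro2, dtype=float))
    a1 = np.atleast_2d(np.asarray(data.accel1, dtype=float))
    a2 = np.atleast_2d(np.asarray(data.accel2, dtype=float))
    ng, na = len(g1), len(a1)

    J = np.empty((ng + na, 4))
    # gyro rows: d e_w / d j_i chained through d j_i / d (theta_i, phi_i)
    J[:ng, 0:2] = w.w_omega * (_cross_norm_grad(g1, j1) @ D1)
    J[:ng, 2:4] = -w.w_omega * (_cross_norm_grad(g2, j2) @ D2)
    # accel rows: d e_a / d j = (y_a1, -y_a2)
    J[ng:, 0:2] = w.w_a * (a1 @ D1)
    J[ng:, 2:4] = -w.w_a * (a2 @ D2)

    n1 = np.linalg.norm(np.cross(g1, j1), axis=-1)
    n2 = np.linalg.norm(np.cross(g2, j2), axis=-1)
    e = np.concatenate([w.w_omega * (n1 - n2), w.w_a * (a1 @ j1 - a2 @ j2)])
    return J, e


# --------------------------------------------------------------------------
# error metric
# --------------------------------------------------------------------------

def angular_deviation(v1, v2) -> float:
    """Positive angle between two vectors, in degrees, in [0, 180].

    The cosine is clamped to [-1, 1] before the arccos so that rounding in
    the dot product of near-(anti)parallel unit vectors cannot produce NaN.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("angular deviation is undefined for zero vectors")
    c = np.clip(float(v1 @ v2) / (n1 * n2), -1.0, 1.0)
    return math.degrees(math.acos(c))
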