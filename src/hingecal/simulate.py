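"""Rigid-body hinge-joint simulator.

The simulator is the sole data source for testing the calibration pipeline.
It builds each sensor's orientation as a product of elementary rotations,

    R_i(t) = R_base(t) * Rot(jB, alpha_i(t)) * C_i,

where ``R_base`` is a carrier rotation shared by both segments, ``jB`` is the
hinge axis in the carrier frame, ``alpha_i`` is segment *i*'s joint angle and
``C_i`` is the constant mounting rotation taking the configured true axis
``j_i`` (sensor frame) onto ``jB``.  By construction both sensors transport
their axis onto the same global vector at every instant, so the gyroscope
constraint holds exactly at the true axes, to machine precision.

Angular velocities and accelerations are obtained in closed form by
differentiating the rotation chain, never by numerical differencing.  IMU
measurements are synthesized from the standard models: the gyroscope reads
the sensor-frame angular velocity plus a constant bias and Gaussian noise;
the accelerometer reads the joint-centre acceleration and gravity rotated
into the sensor frame plus the rotational term ``K(w, wd) r`` from the
sensor's constant offset ``r`` to the joint centre, plus bias and noise.

Fourteen motion classes mirror a benchmark protocol on a mechanical hinge
joint: stationary, stiff-joint rotation (joint locked), sequential rotation
(one segment at a time), simultaneous planar rotation and free rotation, in
slow and fast variants, with horizontal / tilting / free axis orientations.
Four scenario orderings arrange these motions so that the informative samples
arrive early, late, or diluted among non-informative ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .kinematics import SampleBatch, rotation_operator_K

__all__ = [
    "SimConfig",
    "MotionSpec",
    "ScenarioEntry",
    "ScenarioSpec",
    "GroundTruth",
    "SCENARIOS",
    "motion_spec",
    "generate_trajectory",
    "synthesize_measurements",
    "build_scenario",
    "iter_seconds",
    "write_recording",
    "read_recording",
]

CSV_COLUMNS = ["t", "g1x", "g1y", "g1z", "a1x", "a1y", "a1z",
               "g2x", "g2y", "g2z", "a2x", "a2y", "a2z"]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    Defaults reproduce the benchmark rig: 50 Hz sampling, true axis (0, 1, 0)
    in both sensor frames, gravity 9.82 m/s^2.  Noise levels are
    representative MEMS figures; joint-centre offsets are nonzero so the
    approximate accelerometer constraint is genuinely approximate during
    fast motion.  ``joint_translation_amplitude`` is the displacement (m) of
    the hand-held joint centre during non-stationary motions; its
    acceleration cancels in the residual only under the correct sign
    pairing, which is what lets the accelerometer disambiguate the pairing
    even when gravity is perpendicular to the axis.
    """

    sample_rate: float = 50.0
    true_axis_1: tuple = (0.0, 1.0, 0.0)
    true_axis_2: tuple = (0.0, 1.0, 0.0)
    r1: tuple = (0.0, 0.0, 0.1)
    r2: tuple = (0.0, 0.0, -0.1)
    gyro_noise_std: float = 0.01
    accel_noise_std: float = 0.1
    gyro_bias_1: tuple = (0.0, 0.0, 0.0)
    gyro_bias_2: tuple = (0.0, 0.0, 0.0)
    accel_bias_1: tuple = (0.0, 0.0, 0.0)
    accel_bias_2: tuple = (0.0, 0.0, 0.0)
    gravity_magnitude: float = 9.82
    joint_translation_amplitude: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.gyro_noise_std < 0 or self.accel_noise_std < 0:
            raise ValueError("noise stds must be non-negative")
        for a in (self.true_axis_1, self.true_axis_2):
            if abs(np.linalg.norm(np.asarray(a, dtype=float)) - 1.0) > 1e-9:
                raise ValueError("true axes must be unit vectors")

    def noiseless(self) -> "SimConfig":
        return replace(self, gyro_noise_std=0.0, accel_noise_std=0.0)


@dataclass(frozen=True)
class MotionSpec:
    """One motion class instance.

    ``kind`` is one of stationary, stiff_rotation, sequential_rotation,
    simultaneous_planar, free_rotation.  ``speed`` 'fast' scales all rates by
    ``fast_factor``.  ``axis_orientation``: 'horizontal' keeps the hinge axis
    perpendicular to gravity, 'tilting' maintains a 45 degree angle to
    gravity while the carrier precesses, 'free' lets the carrier tumble.
    """

    kind: str
    duration: float = 50.0
    speed: str = "slow"
    axis_orientation: str = "horizontal"
    fast_factor: float = 3.0

    def __post_init__(self):
        if self.kind not in {"stationary", "stiff_rotation", "sequential_rotation",
                             "simultaneous_planar", "free_rotation"}:
            raise ValueError(f"unknown motion kind: {self.kind}")
        if self.speed not in {"slow", "fast"}:
            raise ValueError(f"unknown speed: {self.speed}")
        if self.axis_orientation not in {"horizontal", "tilting", "free"}:
            raise ValueError(f"unknown axis orientation: {self.axis_orientation}")
        if not self.duration > 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free kinematic state of both sensors over one trajectory."""

    times: np.ndarray          # (N,) s
    R1: np.ndarray             # (N, 3, 3) sensor-1-to-global
    R2: np.ndarray             # (N, 3, 3)
    omega1: np.ndarray         # (N, 3) rad/s, sensor frame
    omega2: np.ndarray
    omegadot1: np.ndarray      # (N, 3) rad/s^2, sensor frame
    omegadot2: np.ndarray
    a0: np.ndarray             # (N, 3) m/s^2, joint-centre acceleration, global
    j1: np.ndarray             # (3,) true axis, sensor-1 frame
    j2: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    def slice(self, start: int, stop: int | None = None) -> "GroundTruth":
        sl = slice(start, stop)
        return GroundTruth(self.times[sl], self.R1[sl], self.R2[sl],
                           self.omega1[sl], self.omega2[sl],
                           self.omegadot1[sl], self.omegadot2[sl],
                           self.a0[sl], self.j1, self.j2)

    @classmethod
    def concatenate(cls, parts, sample_rate: float) -> "GroundTruth":
        parts = list(parts)
        n = sum(len(p) for p in parts)
        times = np.arange(n) / sample_rate
        cat = lambda name: np.concatenate([getattr(p, name) for p in parts])
        return cls(times, cat("R1"), cat("R2"), cat("omega1"), cat("omega2"),
                   cat("omegadot1"), cat("omegadot2"), cat("a0"),
                   parts[0].j1, parts[0].j2)


# --------------------------------------------------------------------------
# closed-form rotation chains
# --------------------------------------------------------------------------

class _Profile:
    """Windowed sinusoid angle profile ``A * env(t) * sin(2 pi f t + phase)``
    with closed-form first and second derivatives.  ``env`` is a Hann window
    on ``[t0, t1]`` (zero value and slope at both ends) or 1 everywhere."""

    def __init__(self, amplitude=0.0, freq=0.0, phase=0.0, window=None, offset=0.0):
        self.A = amplitude
        self.f = freq
        self.phase = phase
        self.window = window
        self.offset = offset

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        w = 2 * math.pi * self.f
        s = np.sin(w * t + self.phase)
        c = np.cos(w * t + self.phase)
        val = self.A * s + self.offset
        d1 = self.A * w * c
        d2 = -self.A * w * w * s
        if self.window is not None:
            t0, t1 = self.window
            T = t1 - t0
            u = 2 * math.pi * (t - t0) / T
            inside = (t >= t0) & (t <= t1)
            env = np.where(inside, 0.5 * (1 - np.cos(u)), 0.0)
            env1 = np.where(inside, math.pi / T * np.sin(u), 0.0)
            env2 = np.where(inside, 2 * (math.pi / T) ** 2 * np.cos(u), 0.0)
            base = self.A * s
            val = env * base + self.offset
            d1n = env1 * base + env * self.A * w * c
            d2n = (env2 * base + 2 * env1 * self.A * w * c
                   + env * (-self.A * w * w * s))
            d1, d2 = d1n, d2n
        return val, d1, d2


_ZERO = _Profile()


def _chain(t: np.ndarray, factors) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the product of rotations about fixed axes.

    ``factors`` is a list of ``(axis, profile)``; the product is taken left to
    right.  Returns ``(R, omega_G, omegadot_G)`` where ``omega_G`` is the
    angular velocity of the product frame expressed in the global frame,
    accumulated with the standard composition rule
    ``omega' = omega_P + gamma' * (P u)``.
    """
    n = len(t)
    R = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    w = np.zeros((n, 3))
    wd = np.zeros((n, 3))
    for axis, profile in factors:
        u = _unit(axis)
        gamma, d1, d2 = profile(t)
        Rm = Rotation.from_rotvec(np.outer(gamma, u)).as_matrix()
        Pu = R @ u                                  # (N, 3)
        w_new = w + d1[:, None] * Pu
        wd_new = wd + d2[:, None] * Pu + d1[:, None] * np.cross(w, Pu)
        R = R @ Rm
        w, wd = w_new, wd_new
    return R, w, wd


def _rotation_between(a, b) -> np.ndarray:
    """Minimal rotation matrix taking unit vector ``a`` onto ``b``."""
    a = _unit(a)
    b = _unit(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis perpendicular to a
        p = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(p) < 1e-6:
            p = np.cross(a, [0.0, 1.0, 0.0])
        return Rotation.from_rotvec(math.pi * _unit(p)).as_matrix()
    return Rotation.from_rotvec(_unit(v) * math.acos(np.clip(c, -1, 1))).as_matrix()


# --------------------------------------------------------------------------
# trajectory generation
# --------------------------------------------------------------------------

_JB = np.array([0.0, 1.0, 0.0])     # hinge axis in the carrier frame
_AMPLITUDE = math.pi / 4            # 45 deg joint-angle swings
_F_SLOW = 0.25                      # Hz, segment-rotation rate


def _carrier_factors(spec: MotionSpec, sf: float):
    """Carrier-rotation factors for the configured axis orientation.

    For planar motions the carrier is constant (the motion stays in one
    plane); for tilting motions it precesses about gravity keeping the axis
    45 deg from vertical; for free motions it tumbles about two axes.
    """
    planar = spec.kind in {"simultaneous_planar", "sequential_rotation",
                           "stationary"}
    if spec.axis_orientation == "horizontal":
        return []
    if spec.axis_orientation == "tilting":
        tilt = [(np.array([1.0, 0.0, 0.0]), _Profile(offset=math.pi / 4))]
        if planar:
            return tilt
        return [(np.array([0.0, 0.0, 1.0]),
                 _Profile(amplitude=1.0, freq=0.1 * sf))] + tilt
    # free orientation
    return [(np.array([0.0, 0.0, 1.0]), _Profile(amplitude=1.0, freq=0.12 * sf)),
            (np.array([1.0, 0.0, 0.0]),
             _Profile(amplitude=0.8, freq=0.17 * sf, phase=0.7))]


def _segment_profiles(spec: MotionSpec, sf: float) -> tuple[_Profile, _Profile]:
    f = _F_SLOW * sf
    A = _AMPLITUDE
    T = spec.duration
    if spec.kind == "stationary":
        return _ZERO, _ZERO
    if spec.kind == "stiff_rotation":
        # identical joint angles: the joint is locked but the pair still
        # swings about the axis while the carrier rotates
        p = _Profile(amplitude=A, freq=f)
        return p, p
    if spec.kind == "sequential_rotation":
        return (_Profile(amplitude=A, freq=f, window=(0.0, T / 2)),
                _Profile(amplitude=A, freq=f, window=(T / 2, T)))
    if spec.kind == "simultaneous_planar":
        # different frequencies at equal peak rates: the segments alternate
        # in angular-rate dominance (equal-magnitude counter-rotation would
        # make the rate magnitudes identical, a degenerate case)
        return (_Profile(amplitude=A, freq=f),
                _Profile(amplitude=1.5 * A, freq=f * 2 / 3, phase=0.9))
    # free_rotation
    return (_Profile(amplitude=A, freq=f),
            _Profile(amplitude=1.25 * A, freq=0.8 * f, phase=1.3))


def generate_trajectory(spec: MotionSpec, cfg: SimConfig) -> GroundTruth:
    """Generate the noise-free kinematic truth for one motion."""
    n = int(round(spec.duration * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    sf = spec.fast_factor if spec.speed == "fast" else 1.0

    carrier = _carrier_factors(spec, sf)
    p1, p2 = _segment_profiles(spec, sf)
    j1 = _unit(cfg.true_axis_1)
    j2 = _unit(cfg.true_axis_2)
    C1 = _rotation_between(j1, _JB)     # mounting rotation: C_i j_i = jB
    C2 = _rotation_between(j2, _JB)

    out = {}
    for i, (prof, C) in enumerate([(p1, C1), (p2, C2)], start=1):
        R, wG, wdG = _chain(t, carrier + [(_JB, prof)])
        Ri = R @ C                        # constant right factor; omega unchanged
        out[f"R{i}"] = Ri
        # sensor-frame angular velocity / acceleration
        out[f"omega{i}"] = np.einsum("nij,ni->nj", Ri, wG)
        out[f"omegadot{i}"] = np.einsum("nij,ni->nj", Ri, wdG)

    # joint-centre translation: stationary motions keep the rig at rest,
    # everything else sways it gently (closed-form second derivative of a
    # three-component sinusoidal displacement)
    a0 = np.zeros((n, 3))
    if spec.kind != "stationary":
        amp = cfg.joint_translation_amplitude
        for c, (fc, ph) in enumerate([(0.31, 0.0), (0.43, 1.1), (0.37, 2.3)]):
            wc = 2 * math.pi * fc * sf
            a0[:, c] = -amp * wc * wc * np.sin(wc * t + ph)

    return GroundTruth(times=t, R1=out["R1"], R2=out["R2"],
                       omega1=out["omega1"], omega2=out["omega2"],
                       omegadot1=out["omegadot1"], omegadot2=out["omegadot2"],
                       a0=a0, j1=j1, j2=j2)


def synthesize_measurements(truth: GroundTruth, cfg: SimConfig,
                            rng: np.random.Generator | None = None) -> SampleBatch:
    """Synthesize IMU measurements from kinematic truth.

    Gyroscope: ``y_w = omega + b_w + e_w``; accelerometer:
    ``y_a = R^T (a0 + g) + K(omega, omegadot) r + b_a + e_a`` with the
    gravity vector ``g = (0, 0, g0)`` in the global frame.  Noise is i.i.d.
    Gaussian, reproducible from the configured seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(truth)
    g = np.array([0.0, 0.0, cfg.gravity_magnitude])
    chans = {}
    for i in (1, 2):
        R = getattr(truth, f"R{i}")
        w = getattr(truth, f"omega{i}")
        wd = getattr(truth, f"omegadot{i}")
        r = np.asarray(getattr(cfg, f"r{i}"), dtype=float)
        bw = np.asarray(getattr(cfg, f"gyro_bias_{i}"), dtype=float)
        ba = np.asarray(getattr(cfg, f"accel_bias_{i}"), dtype=float)
        gyro = w + bw + cfg.gyro_noise_std * rng.standard_normal((n, 3))
        spin = np.einsum("nij,j->ni", rotation_operator_K(w, wd), r)
        accel = (np.einsum("nji,nj->ni", R, truth.a0 + g) + spin + ba
                 + cfg.accel_noise_std * rng.standard_normal((n, 3)))
        chans[f"gyro{i}"] = gyro
        chans[f"accel{i}"] = accel
    return SampleBatch(truth.times, chans["gyro1"], chans["gyro2"],
                       chans["accel1"], chans["accel2"])


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------

#: the 14 motion classes: 1..7 slow, 8..14 the same motions fast
_MOTION_TABLE = {
    1: ("stationary", "horizontal"),
    2: ("stiff_rotation", "free"),
    3: ("sequential_rotation", "horizontal"),
    4: ("sequential_rotation", "tilting"),
    5: ("simultaneous_planar", "horizontal"),
    6: ("simultaneous_planar", "tilting"),
    7: ("free_rotation", "free"),
}


def motion_spec(index: int, duration: float = 50.0) -> MotionSpec:
    """The numbered motion classes: 1-7 slow, 8-14 their fast variants."""
    if not 1 <= index <= 14:
        raise ValueError("motion index must be in 1..14")
    base = (index - 1) % 7 + 1
    kind, orient = _MOTION_TABLE[base]
    speed = "fast" if index > 7 else "slow"
    return MotionSpec(kind=kind, duration=duration, speed=speed,
                      axis_orientation=orient)


@dataclass(frozen=True)
class ScenarioEntry:
    """One scenario element: motion index plus the retained fraction of the
    motion (truncations and first/second-half splits)."""

    motion: int
    start: float = 0.0
    stop: float = 1.0


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    entries: tuple = field(default_factory=tuple)


def _entries(*items) -> tuple:
    out = []
    for it in items:
        out.append(ScenarioEntry(*it) if isinstance(it, tuple) else ScenarioEntry(it))
    return tuple(out)


#: The four scenario orderings.  Fractions reproduce the benchmark
#: truncations at 50 s motions: 0.2 of a motion = 10 s (500 samples at
#: 50 Hz), 0.4 = 20 s (1000 samples); halves split a motion in two.
SCENARIOS = {
    "scenario1": ScenarioSpec("scenario1", _entries(*range(1, 15))),
    "scenario2": ScenarioSpec("scenario2", _entries(
        1, (3, 0.0, 0.2), (10, 0.0, 0.2), 8, 2, 9, 3, 10, 4, 11, 5, 12, 6, 13, 7, 14)),
    "scenario3": ScenarioSpec("scenario3", _entries((6, 0.0, 0.4), 1, 8, 2, 9)),
    "scenario4": ScenarioSpec("scenario4", _entries(
        1, 8, (2, 0.0, 0.5), (9, 0.0, 0.5), (6, 0.0, 0.4), (2, 0.5, 1.0), (9, 0.5, 1.0))),
}


@dataclass(frozen=True)
class ScenarioData:
    batch: SampleBatch
    truth: GroundTruth
    labels: np.ndarray          # (N,) motion index per sample


def build_scenario(scenario: ScenarioSpec | str, cfg: SimConfig,
                   motion_duration: float = 50.0) -> ScenarioData:
    """Simulate a scenario: concatenated motions with the stated truncations,
    one shared noise stream, globally rebased timestamps."""
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise ValueError(f"unknown scenario: {scenario!r}") from None
    parts, labels = [], []
    for entry in scenario.entries:
        spec = motion_spec(entry.motion, duration=motion_duration)
        truth = generate_trajectory(spec, cfg)
        n = len(truth)
        lo, hi = int(round(entry.start * n)), int(round(entry.stop * n))
        part = truth.slice(lo, hi)
        parts.append(part)
        labels.append(np.full(len(part), entry.motion, dtype=int))
    truth = GroundTruth.concatenate(parts, cfg.sample_rate)
    batch = synthesize_measurements(truth, cfg)
    return ScenarioData(batch=batch, truth=truth,
                        labels=np.concatenate(labels))


def iter_seconds(batch: SampleBatch, sample_rate: float | None = None):
    """Yield the recording in consecutive 1 s increments (the per-batch
    granularity of the streaming protocol)."""
    if sample_rate is None:
        dt = np.median(np.diff(batch.times)) if len(batch) > 1 else 1.0
        sample_rate = 1.0 / dt
    per = max(1, int(round(sample_rate)))
    for lo in range(0, len(batch), per):
        yield batch.slice(lo, min(lo + per, len(batch)))


# --------------------------------------------------------------------------
# CSV interface
# --------------------------------------------------------------------------

def write_recording(path, batch: SampleBatch) -> None:
    """Write a recording as CSV, one row per sample, SI units."""
    df = pd.DataFrame(
        np.column_stack([batch.times, batch.gyro1, batch.accel1,
                         batch.gyro2, batch.accel2]),
        columns=CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")


def read_recording(path) -> SampleBatch:
    """Read a recording CSV written by :func:`write_recording`."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"recording CSV is missing columns: {missing}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("recording timestamps must be strictly increasing")
    get = lambda cols: df[cols].to_numpy(dtype=float)
    return SampleBatch(t, get(["g1x", "g1y", "g1z"]), get(["g2x", "g2y", "g2z"]),
                       get(["a1x", "a1y", "a1z"]), get(["a2x", "a2y", "a2z"]))
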