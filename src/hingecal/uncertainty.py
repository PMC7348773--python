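"""Local and global uncertainty quantification with an acceptance rule.

A calibration is only useful if the system can tell *when* it is reliable.
Two complementary statistics are computed for every streaming estimate:

* **Local** — the parameter covariance ``Px = (Js^T Js)^-1`` from the
  residual-scaled Jacobian at the estimate, propagated by Monte Carlo
  through the angular deviation of each axis from the estimate.  The metric
  is the mean plus two standard deviations of that deviation, per axis.
  A (near-)singular information matrix signals non-identifiability and is
  reported as an infinite metric, never as an error.
* **Global** — consecutive estimates from independently randomized starts
  are compared via the maximum sequential angular deviation (SEQAD).  If the
  optimizer keeps landing on the same axis pair from random starts, the
  found minimum is trusted to be global.

An estimate is accepted as soon as both axes' local metrics and the last
``n_min`` SEQAD values all lie below the accuracy threshold ``e_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimate import EstimatorConfig, estimate_joint_axis, random_initialization
from .kinematics import (AxisParams, SampleBatch, angular_deviation,
                         residual_jacobian, spherical_to_axis)
from .select import SelectionConfig, SelectionState, update_selection

__all__ = [
    "UncertaintyConfig",
    "UncertaintyReport",
    "SequentialState",
    "BatchRecord",
    "CalibrationOutcome",
    "angular_deviation",
    "local_covariance",
    "monte_carlo_ad",
    "sign_consistent",
    "seqad",
    "run_acceptance",
]

_STD_FLOOR = 1e-12
_COND_LIMIT = 1e12


@dataclass(frozen=True)
class UncertaintyConfig:
    """Acceptance-rule settings: Monte-Carlo sample count ``mc_samples``,
    accuracy threshold ``e_max`` (degrees), required run length ``n_min`` of
    consecutive consistent estimates, and the seed driving both the random
    starts and the Monte-Carlo draws."""

    mc_samples: int = 1000
    e_max: float = 3.0
    n_min: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.mc_samples < 2 or not self.e_max > 0 or self.n_min < 1:
            raise ValueError("invalid uncertainty configuration")


@dataclass(frozen=True)
class UncertaintyReport:
    Px: np.ndarray                 # 4x4 parameter covariance
    mu_z: np.ndarray               # (2,) mean axis deviation, deg
    sigma_z: np.ndarray            # (2,) deviation std, deg
    local_metric: np.ndarray       # (2,) mu + 2 sigma, deg
    seqad: float                   # deg
    accepted: bool


@dataclass
class SequentialState:
    """Rolling state for the global-uncertainty test."""

    prev: tuple | None = None      # (j1, j2) of the previous sign-aligned estimate
    history: list = field(default_factory=list)   # recent SEQAD values

    def push(self, pair: tuple, n_min: int) -> float:
        pair = sign_consistent(pair, self.prev)
        value = seqad(pair, self.prev)
        self.prev = pair
        self.history.append(value)
        if len(self.history) > n_min:
            del self.history[:-n_min]
        return value

    def global_pass(self, e_max: float, n_min: int) -> bool:
        return len(self.history) >= n_min and max(self.history) < e_max


def local_covariance(x_hat, data, w) -> np.ndarray:
    """Asymptotic parameter covariance from the scaled Jacobian.

    Gyro rows are divided by the sample standard deviation of the gyro
    residuals and accel rows by that of the accel residuals (each floored at
    1e-12 so a perfect fit cannot divide by zero); the covariance is the
    inverse of the resulting normal matrix.  If that matrix is singular or
    numerically near-singular the data does not identify the axis and a
    matrix of +inf is returned.
    """
    J, e = residual_jacobian(x_hat, data, w)
    ng = len(np.atleast_2d(data.gyro1))
    Js = J.copy()
    for rows in (slice(0, ng), slice(ng, None)):
        r = e[rows]
        s = float(np.std(r, ddof=1)) if len(r) >= 2 else 0.0
        Js[rows] /= max(s, _STD_FLOOR)
    H = Js.T @ Js
    if not np.all(np.isfinite(H)) or np.linalg.cond(H) > _COND_LIMIT:
        return np.full((4, 4), np.inf)
    return np.linalg.inv(H)


def monte_carlo_ad(x_hat, Px, L: int = 1000,
                   rng: np.random.Generator | int | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo propagation of parameter uncertainty to axis deviation.

    Draws ``L`` parameter vectors from ``N(x_hat, Px)``, maps each to the
    angular deviations of its two axes from the estimate's axes, and returns
    the sample mean and the (unbiased, ddof=1) standard deviation of the two
    deviations, in degrees.  A non-PSD ``Px`` is symmetrized and its negative
    eigenvalues clipped at zero; a non-finite ``Px`` yields infinite moments.
    """
    x = x_hat.as_array() if isinstance(x_hat, AxisParams) else \
        np.asarray(x_hat, dtype=float).reshape(4)
    Px = np.asarray(Px, dtype=float)
    if not np.all(np.isfinite(Px)):
        return np.full(2, np.inf), np.full(2, np.inf)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    S = 0.5 * (Px + Px.T)
    vals, vecs = np.linalg.eigh(S)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    xs = x + rng.standard_normal((L, 4)) @ root.T
    j1s = spherical_to_axis(xs[:, 0], xs[:, 1])
    j2s = spherical_to_axis(xs[:, 2], xs[:, 3])
    j1h = spherical_to_axis(x[0], x[1])
    j2h = spherical_to_axis(x[2], x[3])
    z = np.degrees(np.arccos(np.clip(
        np.stack([j1s @ j1h, j2s @ j2h], axis=1), -1.0, 1.0)))
    return z.mean(axis=0), z.std(axis=0, ddof=1)


def sign_consistent(pair: tuple, prev: tuple | None) -> tuple:
    """Resolve the global sign of an axis-pair estimate against its
    predecessor.

    Returns ``+(j1, j2)`` or ``-(j1, j2)``, whichever makes the
    better-matching axis most consistent with the previous estimate.  Only
    one axis is forced consistent; a sign flip of the *other* axis survives
    for SEQAD to detect.  The first estimate is returned unchanged.
    """
    j1, j2 = (np.asarray(v, dtype=float) for v in pair)
    if prev is None:
        return (j1, j2)
    p1, p2 = prev
    score_pos = min(angular_deviation(j1, p1), angular_deviation(j2, p2))
    score_neg = min(angular_deviation(-j1, p1), angular_deviation(-j2, p2))
    if score_neg < score_pos:
        return (-j1, -j2)
    return (j1, j2)


def seqad(current: tuple | None, previous: tuple | None) -> float:
    """Maximum per-axis angular deviation between consecutive sign-aligned
    estimates, in degrees; 180 when there is no previous estimate."""
    if current is None or previous is None:
        return 180.0
    return max(angular_deviation(current[0], previous[0]),
               angular_deviation(current[1], previous[1]))


@dataclass(frozen=True)
class BatchRecord:
    """Per-second diagnostics of the streaming calibration."""

    t: float
    n_total: int
    n_gyro: int
    n_accel: int
    final_cost: float
    local_metric: tuple
    seqad: float
    accepted: bool


@dataclass(frozen=True)
class CalibrationOutcome:
    accepted: bool
    j1: np.ndarray | None
    j2: np.ndarray | None
    x_hat: AxisParams | None
    t_accept: float | None
    records: list


def run_acceptance(batch_stream, sel_cfg: SelectionConfig | None,
                   est_cfg: EstimatorConfig | None = None,
                   unc_cfg: UncertaintyConfig | None = None) -> CalibrationOutcome:
    """Streaming calibration with the acceptance rule.

    ``batch_stream`` yields consecutive increments of the recording (one per
    second); the cumulative data grows by one batch per step.  Each step runs
    sample selection, estimates the axis pair from a fresh area-uniform
    random start, sign-aligns it against the previous estimate and evaluates
    both uncertainty criteria.  Returns as soon as an estimate passes both;
    otherwise reports 'exhausted' (``accepted=False``) when the stream ends.
    ``sel_cfg=None`` disables selection and uses all samples.
    """
    if est_cfg is None:
        est_cfg = EstimatorConfig()
    if unc_cfg is None:
        unc_cfg = UncertaintyConfig()
    rng = np.random.default_rng(unc_cfg.seed)
    w = est_cfg.weights()
    sel_state = SelectionState()
    seq = SequentialState()
    records: list[BatchRecord] = []
    chunks = []
    n_total = 0

    for batch in batch_stream:
        chunks.append(batch)
        n_total += len(batch)
        t_now = float(batch.times[-1]) if len(batch) else 0.0
        if sel_cfg is not None:
            update_selection(batch, sel_cfg, sel_state)
            gyro_idx, accel_idx = sel_state.gyro_retained, sel_state.accel_retained
        else:
            gyro_idx = accel_idx = np.arange(n_total)
        if len(gyro_idx) + len(accel_idx) < 4:
            records.append(BatchRecord(t_now, n_total, len(gyro_idx),
                                       len(accel_idx), np.nan,
                                       (np.inf, np.inf), 180.0, False))
            continue
        full = chunks[0] if len(chunks) == 1 else SampleBatch.concatenate(chunks)
        chunks = [full]
        data = full.take(gyro_idx, accel_idx)

        result = estimate_joint_axis(data, random_initialization(rng), est_cfg)
        sq = seq.push((result.j1_hat, result.j2_hat), unc_cfg.n_min)
        j1, j2 = seq.prev

        Px = local_covariance(result.x_hat, data, w)
        mu, sigma = monte_carlo_ad(result.x_hat, Px, unc_cfg.mc_samples, rng)
        metric = mu + 2.0 * sigma
        local_pass = bool(np.all(np.isfinite(metric)) and
                          np.all(metric < unc_cfg.e_max))
        accept = local_pass and seq.global_pass(unc_cfg.e_max, unc_cfg.n_min)
        records.append(BatchRecord(t_now, n_total, len(gyro_idx),
                                   len(accel_idx), result.final_cost,
                                   tuple(float(m) for m in metric), sq, accept))
        if accept:
            return CalibrationOutcome(True, j1, j2, result.x_hat, t_now, records)
    return CalibrationOutcome(False, None, None, None, None, records)
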