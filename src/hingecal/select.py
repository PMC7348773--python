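"""Information-driven sample selection.

Arbitrary recordings are dominated by samples that carry no information about
the hinge axis (stationary segments, stiff-joint motion) or that repeat
information already collected.  Two per-channel selectors bound the problem
size at ``n_max`` samples each while preferentially keeping the informative
ones:

* **Gyroscope** — each sample is scored by the signed difference of the two
  sensors' angular-rate magnitudes, conservatively taken as the
  smallest-magnitude difference within a short window (so isolated outliers
  from imperfect rigidity cannot buy their way in).  The ``n_max/2`` most
  positive (sensor-1-dominant) and ``n_max/2`` most negative
  (sensor-2-dominant) scores are kept, guaranteeing excitation from both
  segments.
* **Accelerometer** — samples are first discarded when the windowed
  angular-rate energy of *both* sensors exceeds a threshold (the
  accelerometer constraint is only trustworthy when at least one sensor is
  near-stationary).  The survivors are then thinned by repeatedly removing
  the worst-penalty sample among those most coherent with the dominant
  right-singular vector of the stacked constraint matrix, which preserves
  directional diversity and keeps the least-squares problem well separated
  from its null space.

Both selectors cache per-sample scores so that streaming data only costs the
scores of previously unseen samples (plus the window overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import SampleBatch

__all__ = [
    "SelectionConfig",
    "SelectionState",
    "gyro_score",
    "select_gyro",
    "angular_rate_energy",
    "accel_penalty",
    "coherence",
    "select_accel",
    "update_selection",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Selection settings.

    ``n_max``: per-channel sample budget (even).  ``n``: window half-width
    in samples for the score and energy statistics.  ``energy_threshold``:
    angular-rate energy (rad^2/s^2) above which accelerometer samples are
    discarded outright — about ten times the zero-velocity-detection
    threshold used in gait analysis, so only clearly moving samples are
    dropped.  The coherence cutoff 0.5 is structural, not tunable.
    """

    n_max: int = 1000
    n: int = 21
    energy_threshold: float = 1.0
    coherence_cutoff: float = 0.5

    def __post_init__(self):
        if self.n_max < 2 or self.n_max % 2:
            raise ValueError("n_max must be even and >= 2")
        if self.n < 1:
            raise ValueError("window half-width n must be >= 1")
        if not self.energy_threshold > 0:
            raise ValueError("energy_threshold must be positive")


@dataclass
class SelectionState:
    """Cached per-sample statistics plus the retained index sets.

    Scores are keyed by original sample index and only recomputed for the
    window overlapping newly arrived data; samples once removed by the
    accelerometer thinning loop stay removed.
    """

    n_seen: int = 0
    delta_omega: np.ndarray = field(default_factory=lambda: np.empty(0))
    gyro_sq1: np.ndarray = field(default_factory=lambda: np.empty(0))
    gyro_sq2: np.ndarray = field(default_factory=lambda: np.empty(0))
    accel_rows: np.ndarray = field(default_factory=lambda: np.empty((0, 6)))
    s_omega: np.ndarray = field(default_factory=lambda: np.empty(0))
    s_a: np.ndarray = field(default_factory=lambda: np.empty(0))
    gyro_retained: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    accel_retained: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    accel_removed: set = field(default_factory=set)
    fallback_removals: int = 0


# --------------------------------------------------------------------------
# per-sample statistics
# --------------------------------------------------------------------------

def _windowed_conservative(delta: np.ndarray, n: int) -> np.ndarray:
    """For each k, the signed value of smallest magnitude among
    ``delta[k-n .. k+n]`` (window truncated at the edges)."""
    pad = np.pad(delta, n, constant_values=np.inf)
    win = np.lib.stride_tricks.sliding_window_view(pad, 2 * n + 1)
    idx = np.argmin(np.abs(win), axis=1)
    return win[np.arange(len(delta)), idx]


def gyro_score(batch: SampleBatch, n: int = 21) -> np.ndarray:
    """Conservative independent-rotation score per sample.

    ``delta(k) = ||y_w1(k)|| - ||y_w2(k)||`` measures independent segment
    rotation; the score is the smallest-magnitude ``delta`` in the 2n+1
    window around k.
    """
    delta = (np.linalg.norm(batch.gyro1, axis=1)
             - np.linalg.norm(batch.gyro2, axis=1))
    return _windowed_conservative(delta, n)


def _windowed_energy(sq: np.ndarray, n: int) -> np.ndarray:
    """Mean of ``sq`` over the centred 2n+1 window; +inf where the window
    would run off either edge."""
    N = len(sq)
    out = np.full(N, np.inf)
    if N >= 2 * n + 1:
        c = np.concatenate([[0.0], np.cumsum(sq)])
        out[n:N - n] = (c[2 * n + 1:] - c[:N - 2 * n]) / (2 * n + 1)
    return out


def angular_rate_energy(batch: SampleBatch, sensor: int, n: int = 21) -> np.ndarray:
    """Windowed mean squared angular-rate magnitude of one sensor
    (rad^2/s^2); +inf at the edges where the window is incomplete."""
    if sensor not in (1, 2):
        raise ValueError("sensor must be 1 or 2")
    g = batch.gyro1 if sensor == 1 else batch.gyro2
    return _windowed_energy(np.einsum("ij,ij->i", g, g), n)


def accel_penalty(batch: SampleBatch, n: int = 21) -> np.ndarray:
    """Penalty per accelerometer sample: the smaller of the two sensors'
    angular-rate energies (one near-stationary sensor suffices for the
    constraint to be trustworthy)."""
    return np.minimum(angular_rate_energy(batch, 1, n),
                      angular_rate_energy(batch, 2, n))


def coherence(accel_rows: np.ndarray) -> np.ndarray:
    """Alignment of each stacked constraint row with the dominant
    right-singular vector.

    ``accel_rows`` holds rows ``A_k = (y_a1^T, -y_a2^T)``; the coherence is
    ``|A_k w1| / ||A_k||`` with ``w1`` the first right-singular vector of the
    stack.  Values lie in [0, 1]; zero-norm rows get coherence 0.
    """
    A = np.atleast_2d(np.asarray(accel_rows, dtype=float))
    norms = np.linalg.norm(A, axis=1)
    if not np.any(norms > 0):
        raise ValueError("coherence requires at least one nonzero row")
    _, _, Vt = np.linalg.svd(A, full_matrices=False)
    c = np.abs(A @ Vt[0])
    out = np.zeros(len(A))
    nz = norms > 0
    out[nz] = c[nz] / norms[nz]
    return out


# --------------------------------------------------------------------------
# selection over candidate index sets
# --------------------------------------------------------------------------

def _gyro_pick(scores: np.ndarray, candidates: np.ndarray, n_max: int) -> np.ndarray:
    """Keep the n_max/2 most positive and n_max/2 most negative scores among
    ``candidates`` (ties broken by earliest sample index)."""
    if len(candidates) <= n_max:
        return np.sort(candidates)
    s = scores[candidates]
    # stable sort descending by score; among ties the earlier index first
    order = candidates[np.argsort(-s, kind="stable")]
    half = n_max // 2
    return np.sort(np.concatenate([order[:half], order[-half:]]))


def _accel_thin(rows_all: np.ndarray, s_a: np.ndarray, retained: np.ndarray,
                cfg: SelectionConfig, removed: set) -> tuple[np.ndarray, int]:
    """Iteratively remove the worst-penalty sample among those coherent with
    the dominant singular direction until at most n_max remain.  The SVD and
    coherences are recomputed after every removal, since removing rows
    changes the dominant direction.  Returns (retained, fallback count)."""
    retained = np.sort(retained)
    fallback = 0
    while len(retained) > cfg.n_max:
        A = rows_all[retained]
        c = coherence(A)
        eligible = c > cfg.coherence_cutoff
        if np.any(eligible):
            sub = np.where(eligible)[0]
        else:
            # the loop would never terminate otherwise; drop the worst
            # penalty regardless of coherence
            sub = np.arange(len(retained))
            fallback += 1
        worst = sub[np.argmax(s_a[retained[sub]])]
        removed.add(int(retained[worst]))
        retained = np.delete(retained, worst)
    return retained, fallback


def select_gyro(batch: SampleBatch, cfg: SelectionConfig,
                state: SelectionState | None = None) -> np.ndarray:
    """Batch-mode gyroscope selection; returns retained sample indices.

    If a state is given its cached scores are reused and updated in place.
    """
    if state is None:
        scores = gyro_score(batch, cfg.n)
        return _gyro_pick(scores, np.arange(len(batch)), cfg.n_max)
    update_selection(batch, cfg, state, channels=("gyro",))
    return state.gyro_retained


def select_accel(batch: SampleBatch, cfg: SelectionConfig,
                 state: SelectionState | None = None) -> np.ndarray:
    """Batch-mode accelerometer selection; returns retained sample indices.

    First discards every sample whose penalty exceeds the energy threshold,
    then thins the survivors by the coherence rule down to ``n_max``.
    """
    if state is None:
        s_a = accel_penalty(batch, cfg.n)
        keep = np.where(s_a <= cfg.energy_threshold)[0]
        rows = np.hstack([batch.accel1, -batch.accel2])
        retained, _ = _accel_thin(rows, s_a, keep, cfg, set())
        return retained
    update_selection(batch, cfg, state, channels=("accel",))
    return state.accel_retained


def update_selection(new_batch: SampleBatch | None, cfg: SelectionConfig,
                     state: SelectionState,
                     channels=("gyro", "accel")) -> SelectionState:
    """Incorporate a new batch of samples into the selection state.

    Per-sample statistics are appended; scores are recomputed only from
    ``old_N - n`` onward (every window that can overlap the new data).  The
    gyroscope selection is re-run over the previously retained set plus the
    rescored tail — for the two-ends-of-the-sorted-list rule this equals
    batch-mode selection on all data whenever the boundary rescoring does
    not change a score.  The accelerometer pool likewise grows by the newly
    eligible samples and is thinned back to the budget; samples the thinning
    loop already removed stay removed.
    """
    old_n = state.n_seen
    if new_batch is not None and len(new_batch) > 0:
        d_new = (np.linalg.norm(new_batch.gyro1, axis=1)
                 - np.linalg.norm(new_batch.gyro2, axis=1))
        state.delta_omega = np.concatenate([state.delta_omega, d_new])
        state.gyro_sq1 = np.concatenate([
            state.gyro_sq1, np.einsum("ij,ij->i", new_batch.gyro1, new_batch.gyro1)])
        state.gyro_sq2 = np.concatenate([
            state.gyro_sq2, np.einsum("ij,ij->i", new_batch.gyro2, new_batch.gyro2)])
        state.accel_rows = np.vstack([
            state.accel_rows, np.hstack([new_batch.accel1, -new_batch.accel2])])
        state.n_seen += len(new_batch)
    N = state.n_seen
    if N == 0 or N == old_n and old_n > 0 and len(state.s_omega) == N:
        return state

    # rescore the tail whose windows may overlap the new data
    lo = max(0, old_n - cfg.n)
    tail_lo = max(0, lo - cfg.n)        # context needed by the tail windows
    tail_scores = _windowed_conservative(state.delta_omega[tail_lo:], cfg.n)
    state.s_omega = np.concatenate([state.s_omega[:lo], tail_scores[lo - tail_lo:]])
    e1 = _windowed_energy(state.gyro_sq1[tail_lo:], cfg.n)
    e2 = _windowed_energy(state.gyro_sq2[tail_lo:], cfg.n)
    tail_sa = np.minimum(e1, e2)[lo - tail_lo:]
    state.s_a = np.concatenate([state.s_a[:lo], tail_sa])

    if "gyro" in channels:
        # the pick is a sort over cached scores, so it is re-run over all
        # samples: only the scores are expensive enough to be worth caching,
        # and restricting the candidate set would let a sample discarded
        # against a provisional edge score be lost for good
        state.gyro_retained = _gyro_pick(state.s_omega, np.arange(N), cfg.n_max)

    if "accel" in channels:
        pool = np.union1d(state.accel_retained, np.arange(lo, N))
        pool = pool[~np.isin(pool, np.fromiter(state.accel_removed, dtype=int,
                                               count=len(state.accel_removed)))]
        pool = pool[state.s_a[pool] <= cfg.energy_threshold]
        retained, fb = _accel_thin(state.accel_rows, state.s_a, pool, cfg,
                                   state.accel_removed)
        state.accel_retained = retained
        state.fallback_removals += fb
    return state
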