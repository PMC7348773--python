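# Methods

## Problem and model

Two IMUs are rigidly attached to the segments of a hinge (1-DOF) joint.
Each sensor measures, in its own frame, angular velocity
`y_ω = ω + b_ω + e_ω` and specific force
`y_a = Rᵀ(a0 + g) + K(ω, ω̇) r + b_a + e_a`, where `R` is the
sensor-to-global rotation, `a0` the joint-centre acceleration, `g` gravity,
`r` the constant offset from the sensor to the joint centre,
`K(ω, ω̇) r = ω × (ω × r) + ω̇ × r` the rotational acceleration of that
offset, `b` constant biases and `e` i.i.d. Gaussian noise.  Biases and white
noise are the dominant error model for MEMS IMUs; axis misalignment, scale
factors and bias drift are assumed handled by pre-calibration and are out of
scope.

The hinge constrains the two segments to rotate independently only about a
common axis, expressed as constant unit vectors `j1`, `j2` in the two sensor
frames.  Two scalar constraints hold per sample: the perpendicular
angular-rate magnitudes agree, `‖ω1×j1‖ = ‖ω2×j2‖`, and the axis
projections of the measured accelerations agree up to the rotational-offset
terms, `j1ᵀa1 − j2ᵀa2 = j1ᵀK1r1 − j2ᵀK2r2 ≈ 0`.  The joint-centre
acceleration cancels in the projection difference *exactly and only* under
the correct sign pairing of the two axes, which is what allows the
accelerometer to distinguish `(+j1, +j2)` from `(+j1, −j2)`.

## Estimator

The axis pair is parametrized by spherical angles (4 parameters, unit norm
by construction) and estimated by minimizing the weighted sum of squared
constraint residuals.  Numerical choices:

* **Weights.** A single ratio `w0 = w_ω/w_a` with `w_ω = √w0`,
  `w_a = 1/√w0`; default `w0 = 50`.  The weight sweep in the test suite
  confirms the error is flat over `w0 ∈ [10, 10⁵]`; at extreme ratios
  (`10⁹`) the accelerometer term becomes numerically invisible and the sign
  pairing degenerates to a coin flip — reproduced deliberately as a test of
  the failure mode.
* **Solver.** Gauss–Newton with the analytic Jacobian; the normal equations
  are damped with `λ = 10⁻¹² tr(JᵀJ)/4` so that non-informative data
  (singular `JᵀJ`) degrades to a defined pseudo-inverse step instead of
  failing.  Step lengths come from Armijo backtracking (shrink 0.5,
  sufficient-decrease constant 10⁻⁴, floor 10⁻⁸), which makes the cost
  sequence non-increasing.  Termination when the absolute cost change drops
  below `V_tol = 10⁻¹⁰` (no published value exists; this is conservative at
  the simulated noise levels), when no decreasing step exists, or at 200
  iterations (a safety cap on top of the cost-change rule).
* **Gradient singularities.** `∂‖y×j‖/∂j` is undefined where `y×j = 0`
  (stationary samples, or `y ∥ j`); the zero subgradient is used, which is
  in the valid subdifferential and keeps stationary data from injecting
  NaNs.
* **Sign pairing.** After the first solve, the solver restarts at
  `(θ1, φ1, −θ2, φ2+π)` — the parameter image of `(j1, −j2)` — and the
  lower-cost candidate wins.  If the two costs differ by less than
  `10⁻¹² max(1, V)` the result carries a `pairing_ambiguous` flag and the
  first candidate is returned.
* **Angle wrapping** only affects reporting (the cost is periodic): θ is
  folded into [−π/2, π/2], φ into (−π, π], with φ = 0 at the poles.

## Sample selection

Both channels get an independent budget `n_max` (default 1000).

* Gyroscope: per-sample score = the smallest-magnitude value of
  `Δω = ‖y_ω1‖ − ‖y_ω2‖` within the `2n+1`-sample window centred on the
  sample (`n = 21`; windows truncated at the recording edges).  Taking the
  windowed minimum makes the score conservative against isolated rigidity
  violations.  The `n_max/2` highest and `n_max/2` lowest scores are kept,
  so both segments' excitation is represented.  Ties break toward the
  earlier sample.
* Accelerometer: penalty = the smaller of the two sensors' windowed
  angular-rate energies (infinite inside `n` samples of an edge); samples
  with penalty above `E_th = 1 rad²/s²` are dropped outright.  The
  survivors are thinned one at a time: recompute the SVD of the retained
  rows `(y_a1ᵀ, −y_a2ᵀ)`, recompute each row's coherence with the first
  right-singular vector, and remove the worst-penalty row among those with
  coherence above 0.5.  If no row exceeds 0.5 while the set is still over
  budget, the worst-penalty row is removed regardless (the plain rule would
  not terminate); these fallback removals are counted in the selection
  state.
* Streaming: per-sample statistics are cached and only recomputed for the
  window overlapping newly arrived data.  The gyro pick is then re-run as a
  sort over *all* cached scores — restricting candidates to
  "previously retained plus new" would permanently lose samples that were
  displaced by a provisional edge score, and the full sort is cheap.  The
  accelerometer thinning is inherently greedy: removed samples stay
  removed, which is the intended online behaviour.

## Uncertainty quantification and acceptance

* **Local.** The parameter covariance is `(JsᵀJs)⁻¹` where the gyro and
  accel rows of the Jacobian at the estimate are divided by the sample
  standard deviation (ddof 1) of the corresponding residuals, floored at
  10⁻¹² against perfect fits.  If the scaled normal matrix has condition
  number above 10¹² the covariance is reported as +∞ — non-identifiability
  is an answer, not an error.  The covariance is propagated by Monte Carlo
  (`L = 1000` draws, seeded; no published value of L exists) through the
  angular deviation of each perturbed axis from the estimate; the local
  metric is mean + 2 SD per axis, and both axes must pass.
* **Global.** Each second's estimate starts from a fresh area-uniform
  random point (`sin θ ~ U(−1,1)`, `φ ~ U(−π,π)` per axis — area-uniform
  avoids polar bias; the sampling scheme is otherwise a free choice).  The
  new estimate's global sign is aligned with its predecessor (only the
  better-matching axis is forced consistent, so a flip of the other axis
  remains visible), and SEQAD = the larger per-axis deviation between
  consecutive aligned estimates, 180° when there is no predecessor.
* **Acceptance.** An estimate is returned once both local metrics are below
  `E_max` (default 3°) *and* the last `n_min` SEQAD values are all below
  `E_max`.  `n_min = 10` is the recommended setting: the test suite shows
  that at `n_min = 3` a noisy stiff-joint-only stream is occasionally
  accepted (a wrong local minimum can be sharp, and three consecutive
  random starts can land in it), while at `n_min = 10` no stiff-only stream
  is ever accepted across seeds.  With two numerically indistinguishable
  minima, the probability of accepting the wrong one `n_min` times in a row
  is `0.5^n_min`, verified by simulation at `n_min = 1`.

## Simulator

Orientations are built as `R_i(t) = R_base(t) · Rot(jB, α_i(t)) · C_i`: a
carrier rotation shared by both segments, an independent joint angle per
segment about the carrier-frame axis `jB`, and the constant mounting
rotation onto the configured true axis.  Both sensors therefore transport
their axis onto the same global vector at every instant, and angular
velocities/accelerations come from differentiating the rotation chain in
closed form — tests cross-check them against finite differences of the
orientations at O(Δt²).

Choices the recorded benchmark leaves open, fixed once here:

* Joint-angle profiles are sinusoids with amplitude 45°, slow frequency
  0.25 Hz, fast variant ×3; sequential motions use Hann-windowed halves so
  each segment moves alone in its half with smooth derivatives.
* Planar and free motions give the two segments *different* frequencies at
  equal peak rates so that angular-rate dominance alternates between
  sensors; exactly equal counter-rotation would make `Δω ≡ 0`, the one
  (unrealistic) degenerate case of the gyro score.
* The joint centre translates sinusoidally (displacement amplitude 0.08 m,
  three incommensurate frequencies ≈0.3–0.45 Hz, zero when stationary).
  Without it — and with an exactly horizontal axis — gravity projects to
  zero along the axis and the acceleration residual is blind to the sign
  pairing; a hand-held rig always translates.
* Sensor offsets `r1 = (0,0,0.1)`, `r2 = (0,0,−0.1)` m keep the
  acceleration constraint genuinely approximate during fast motion; noise
  defaults (gyro 0.01 rad/s, accel 0.1 m/s², unpublished for the benchmark
  sensors) are representative MEMS figures; gravity 9.82 m/s², sampling
  50 Hz, true axes `(0,1,0)`.
* Scenario truncations are stored as fractions of the motion duration
  (0.2, 0.4, halves), so scenarios scale; at the benchmark's 50 s motions
  they reproduce the printed sample counts exactly (35 000 samples after
  700 s of the first ordering).

What the simulator does *not* emulate: soft-tissue artefacts, sensor-axis
misalignment and scale errors, bias drift, non-rigid joints, and the exact
amplitude/frequency content of the recorded benchmark motions.  Passing
tests therefore demonstrate correctness of the algorithms under the rigid
model with Gaussian noise and constant bias, not performance on human
tissue-mounted sensors.

## Problem sizes used in tests and the reproduction script

Motion segments are simulated at 8–20 s (scenario streams at 10 s per
motion; the sample-selection comparison at the full 50 s, where the
informative motion contains 1000 samples against the 500-sample budget —
at shorter durations the informative motion genuinely cannot fill both
halves of the budget and deselection is incomplete).  Reliability protocols
use 20 repetitions.  These sizes are the package's default evaluation
scale; all drivers accept larger values.

## Known limitations

* The accelerometer selection loop recomputes an SVD per removal; batch
  selection on very long recordings (tens of thousands of over-threshold
  samples) is quadratic and should go through the streaming interface
  instead.
* Gauss–Newton converges slowly (hundreds of iterations) when started far
  from a minimum on wrong-pairing basins; the deterministic 36-start grid
  protocol pays this cost knowingly.
* Per-sample residual weighting is not implemented (scalar weights only);
  the residual API keeps the hook open.
* `run_acceptance` re-estimates from scratch each second by design (the
  consistency of independently initialized estimates *is* the global
  uncertainty signal); there is deliberately no warm start.
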