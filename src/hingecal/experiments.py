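"""Runnable evaluation protocols.

These drivers reproduce the shape of the benchmark evaluations on simulated
data: the residual-weight sweep, the sample-budget comparison, the
acceptance-reliability study and the bias-robustness table.  All of them are
ordinary library functions returning pandas DataFrames or plain dicts; the
command-line ``experiment`` subcommand and the reproduction script are thin
wrappers.  Problem sizes (motion durations, repetition counts, grid sizes)
are arguments so the protocols can be run at reduced scale.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .estimate import (EstimatorConfig, estimate_joint_axis,
                       grid_initializations, maxae, rmsae, signed_axis_errors)
from .kinematics import SampleBatch
from .select import SelectionConfig, SelectionState, update_selection
from .simulate import (SimConfig, build_scenario, generate_trajectory,
                       iter_seconds, motion_spec, synthesize_measurements)
from .uncertainty import UncertaintyConfig, run_acceptance

__all__ = [
    "estimate_from_grid",
    "weight_sweep",
    "sample_size_comparison",
    "acceptance_reliability",
    "wrong_minimum_experiment",
    "bias_robustness",
]


def _simulate_motion(index: int, cfg: SimConfig, duration: float) -> SampleBatch:
    truth = generate_trajectory(motion_spec(index, duration), cfg)
    return synthesize_measurements(truth, cfg)


def estimate_from_grid(batch, est_cfg: EstimatorConfig):
    """Estimate from all 36 deterministic axis-aligned starts."""
    return [estimate_joint_axis(batch, x0, est_cfg)
            for x0 in grid_initializations()]


def weight_sweep(w0_values, motions=(5, 3), duration: float = 10.0,
                 cfg: SimConfig | None = None) -> pd.DataFrame:
    """RMSAE/MAXAE over the 36-start grid for each weight ratio and motion.

    Defaults probe the slow simultaneous-planar (5) and sequential (3)
    motions, the classes for which the weight insensitivity is sharpest.
    """
    if cfg is None:
        cfg = SimConfig()
    j1, j2 = np.asarray(cfg.true_axis_1), np.asarray(cfg.true_axis_2)
    rows = []
    for m in motions:
        batch = _simulate_motion(m, cfg, duration)
        for w0 in w0_values:
            results = estimate_from_grid(batch, EstimatorConfig(w0=float(w0)))
            rows.append({"motion": m, "w0": float(w0),
                         "rmsae_deg": rmsae(j1, j2, results),
                         "maxae_deg": maxae(j1, j2, results),
                         "wrong_pairing_fraction": float(np.mean(
                             [signed_axis_errors(j1, j2, r)[1] > 90.0
                              for r in results]))})
    return pd.DataFrame(rows)


def _final_estimate_errors(stream, sel_cfg, est_cfg, true_j1, true_j2, seed):
    """Run the per-second streaming protocol to the end of the stream and
    return the last estimate's per-axis errors plus the selection state."""
    rng = np.random.default_rng(seed)
    sel_state = SelectionState()
    chunks = []
    last = None
    from .estimate import random_initialization
    batches = list(stream)
    for i, batch in enumerate(batches):
        chunks.append(batch)
        if sel_cfg is not None:
            update_selection(batch, sel_cfg, sel_state)
            gi, ai = sel_state.gyro_retained, sel_state.accel_retained
        else:
            # without a budget every estimate uses all data, so only the
            # final one (the quantity compared) needs computing
            if i < len(batches) - 1:
                continue
            n = sum(len(c) for c in chunks)
            gi = ai = np.arange(n)
        full = chunks[0] if len(chunks) == 1 else SampleBatch.concatenate(chunks)
        chunks = [full]
        if len(gi) + len(ai) < 4:
            continue
        last = estimate_joint_axis(full.take(gi, ai),
                                   random_initialization(rng), est_cfg)
    if last is None:
        raise ValueError("stream produced no estimable data")
    ad1, ad2 = signed_axis_errors(true_j1, true_j2, last)
    return ad1, ad2, sel_state


def sample_size_comparison(scenario: str = "scenario3", n_max_values=(500,),
                           motion_duration: float = 10.0,
                           cfg: SimConfig | None = None,
                           seed: int = 0) -> pd.DataFrame:
    """Final streaming-estimate errors with budgeted selection versus using
    all samples, plus which motions survive in the retained gyro set."""
    if cfg is None:
        cfg = SimConfig(seed=seed)
    data = build_scenario(scenario, cfg, motion_duration=motion_duration)
    j1, j2 = data.truth.j1, data.truth.j2
    rows = []
    for n_max in list(n_max_values) + [None]:
        sel_cfg = None if n_max is None else SelectionConfig(n_max=n_max)
        ad1, ad2, state = _final_estimate_errors(
            iter_seconds(data.batch, cfg.sample_rate), sel_cfg,
            EstimatorConfig(), j1, j2, seed)
        retained_motions = (sorted(set(data.labels[state.gyro_retained]))
                            if sel_cfg is not None else sorted(set(data.labels)))
        rows.append({"n_max": n_max if n_max is not None else 0,
                     "uses_all": n_max is None,
                     "ad1_deg": ad1, "ad2_deg": ad2,
                     "retained_gyro_motions": retained_motions})
    return pd.DataFrame(rows)


def acceptance_reliability(scenario: str = "scenario1", n_reps: int = 20,
                           n_min: int = 10, e_max: float = 3.0,
                           motion_duration: float = 10.0, n_max: int = 1000,
                           cfg: SimConfig | None = None,
                           seed: int = 0) -> pd.DataFrame:
    """Repeat the streaming acceptance protocol with different random-start
    seeds; report per-repetition acceptance and true errors."""
    if cfg is None:
        cfg = SimConfig(seed=seed)
    data = build_scenario(scenario, cfg, motion_duration=motion_duration)
    j1, j2 = data.truth.j1, data.truth.j2
    rows = []
    for rep in range(n_reps):
        outcome = run_acceptance(
            iter_seconds(data.batch, cfg.sample_rate),
            SelectionConfig(n_max=n_max), EstimatorConfig(),
            UncertaintyConfig(n_min=n_min, e_max=e_max, seed=seed + 1 + rep))
        row = {"rep": rep, "accepted": outcome.accepted,
               "t_accept": outcome.t_accept}
        if outcome.accepted:
            from .kinematics import angular_deviation
            a1 = angular_deviation(outcome.j1, j1)
            a2 = angular_deviation(outcome.j2, j2)
            if a1 > 90.0:       # global sign is free; fold it out
                a1 = angular_deviation(-outcome.j1, j1)
                a2 = angular_deviation(-outcome.j2, j2)
            row.update(ad1_deg=a1, ad2_deg=a2)
        rows.append(row)
    return pd.DataFrame(rows)


def wrong_minimum_experiment(n_reps: int = 20, n_min: int = 1,
                             duration: float = 30.0, w0: float = 1e9,
                             seed: int = 0) -> pd.DataFrame:
    """Coin-flip acceptance hazard with two equally deep minima.

    At an extreme gyro weighting the costs of the two sign pairings of a
    planar motion become numerically indistinguishable, so every random
    start lands in either pairing with roughly equal probability.  With a
    short consistency run (``n_min=1``) the first repeat accepts, and about
    half of the accepted estimates carry the wrong pairing (a 180-degree
    error on the second axis).
    """
    cfg = SimConfig(seed=seed)
    truth = generate_trajectory(motion_spec(5, duration), cfg)
    batch = synthesize_measurements(truth, cfg)
    rows = []
    for rep in range(n_reps):
        outcome = run_acceptance(
            iter_seconds(batch, cfg.sample_rate), None,
            EstimatorConfig(w0=w0),
            UncertaintyConfig(n_min=n_min, e_max=3.0, seed=seed + 1 + rep))
        wrong = None
        if outcome.accepted:
            from .kinematics import angular_deviation
            a1 = angular_deviation(outcome.j1, truth.j1)
            j1h, j2h = ((outcome.j1, outcome.j2) if a1 <= 90.0
                        else (-outcome.j1, -outcome.j2))
            wrong = bool(angular_deviation(j2h, truth.j2) > 90.0)
        rows.append({"rep": rep, "accepted": outcome.accepted,
                     "wrong_pairing": wrong})
    return pd.DataFrame(rows)


def bias_robustness(scenarios=("scenario1", "scenario2"), n_reps: int = 10,
                    bias_accel: float = 1.0, bias_gyro_deg: float = 1.0,
                    motion_duration: float = 10.0, n_max: int = 500,
                    e_max: float = 1.0, n_min: int = 10,
                    cfg: SimConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """RMSAE/MAXAE of accepted streaming estimates with and without constant
    sensor biases of fixed magnitude and random direction."""
    if cfg is None:
        cfg = SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    rows = []
    for name in scenarios:
        for with_bias in (False, True):
            ads = []
            accepted = 0
            for rep in range(n_reps):
                run_cfg = cfg
                if with_bias:
                    def unit3():
                        v = rng.standard_normal(3)
                        return tuple(v / np.linalg.norm(v))
                    bw = np.radians(bias_gyro_deg)
                    run_cfg = replace(
                        cfg, seed=int(rng.integers(2**31)),
                        accel_bias_1=tuple(bias_accel * np.asarray(unit3())),
                        accel_bias_2=tuple(bias_accel * np.asarray(unit3())),
                        gyro_bias_1=tuple(bw * np.asarray(unit3())),
                        gyro_bias_2=tuple(bw * np.asarray(unit3())))
                data = build_scenario(name, run_cfg,
                                      motion_duration=motion_duration)
                outcome = run_acceptance(
                    iter_seconds(data.batch, run_cfg.sample_rate),
                    SelectionConfig(n_max=n_max), EstimatorConfig(),
                    UncertaintyConfig(n_min=n_min, e_max=e_max,
                                      seed=seed + 101 + rep))
                if outcome.accepted:
                    accepted += 1
                    from .kinematics import angular_deviation
                    a1 = angular_deviation(outcome.j1, data.truth.j1)
                    j1h, j2h = ((outcome.j1, outcome.j2) if a1 <= 90.0
                                else (-outcome.j1, -outcome.j2))
                    ads.extend([angular_deviation(j1h, data.truth.j1),
                                angular_deviation(j2h, data.truth.j2)])
            rows.append({
                "scenario": name, "bias": with_bias,
                "accepted_fraction": accepted / n_reps,
                "rmsae_deg": float(np.sqrt(np.mean(np.square(ads)))) if ads else np.nan,
                "maxae_deg": float(np.max(ads)) if ads else np.nan})
    return pd.DataFrame(rows)
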