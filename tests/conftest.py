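"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from tirftrace.simulate import OccupancyTrajectory
from tirftrace.spots import Trace
from tirftrace.stepfind import Level, StepEvent, StepModel, StepParams


def ls_changepoints(y: np.ndarray, n_segments: int) -> list:
    """Exhaustive least-squares piecewise-constant fit (dynamic program).

    Independent oracle for the step finder: returns the interior change
    points (frame indices) of the optimal ``n_segments``-segment constant
    fit, minimizing the residual sum of squares exactly.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_cost(i, j):  # cost of y[i:j]
        s = c1[j] - c1[i]
        q = c2[j] - c2[i]
        return q - s * s / (j - i)

    INF = np.inf
    cost = np.full((n_segments + 1, n + 1), INF)
    back = np.zeros((n_segments + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, n_segments + 1):
        for j in range(k, n + 1):
            best, arg = INF, k - 1
            for i in range(k - 1, j):
                c = cost[k - 1, i] + seg_cost(i, j)
                if c < best:
                    best, arg = c, i
            cost[k, j] = best
            back[k, j] = arg
    cps = []
    j = n
    for k in range(n_segments, 0, -1):
        i = back[k, j]
        if k > 1:
            cps.append(i)
        j = i
    return sorted(cps)


def make_staircase_trace(level_values, frames_per_level, dt=0.2, noise_sd=0.0,
                         seed=0, channel_tag="venus", spot_id=0) -> Trace:
    """Piecewise-constant trace with known levels, for detector tests."""
    rng = np.random.default_rng(seed)
    y = np.concatenate([
        np.full(nf, v, dtype=float) for v, nf in zip(level_values, frames_per_level)
    ])
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, size=len(y))
    times = np.arange(len(y)) * dt
    return Trace(spot_id=spot_id, times=times, intensity=y, channel_tag=channel_tag)


def step_model_from_occupancy(
    occ: OccupancyTrajectory, dt: float = 0.2, step: float = 100.0,
    spot_id: int = 0, channel_tag: str = "rhodamine",
) -> StepModel:
    """Exact StepModel of a ground-truth occupancy trajectory.

    Bypasses the detector: converts the frame-sampled occupancy directly
    into levels and unit steps, so kinetics operations can be tested
    against simulator truth alone.
    """
    n = occ.n_bound
    params = StepParams(step_mean=step, step_sd=step * 0.15, min_dwell_s=dt / 2,
                        channel_tag=channel_tag)
    bounds = [0] + [i for i in range(1, len(n)) if n[i] != n[i - 1]] + [len(n)]
    levels, steps = [], []
    for bi in range(len(bounds) - 1):
        lo, hi = bounds[bi], bounds[bi + 1]
        levels.append(Level(lo * dt, hi * dt, float(step * n[lo]), hi - lo))
        if bi > 0:
            delta = int(n[bounds[bi]] - n[bounds[bi] - 1])
            steps.append(StepEvent(
                time_s=bounds[bi] * dt, delta_I=float(step * delta),
                sign=1 if delta > 0 else -1, multiplicity=abs(delta),
                p_value=0.0,
            ))
    return StepModel(spot_id=spot_id, levels=levels, steps=steps, params=params,
                     channel_tag=channel_tag, frame_interval_s=dt)


def merge_short_runs(values: np.ndarray, min_frames: int) -> np.ndarray:
    """Resolution-matched truth: absorb runs shorter than ``min_frames``.

    The derivative-based detector cannot resolve occupancy excursions
    shorter than its blur window; this applies the same dead time to a
    ground-truth frame-sampled trajectory so that noise-induced and
    resolution-induced errors can be separated.
    """
    v = np.asarray(values).copy()
    while True:
        # run-length encode
        bounds = [0] + [i for i in range(1, len(v)) if v[i] != v[i - 1]] + [len(v)]
        runs = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
        if len(runs) <= 1:
            return v
        lengths = [b - a for a, b in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_frames:
            return v
        a, b = runs[shortest]
        if shortest == 0:
            v[a:b] = v[b]
        else:
            v[a:b] = v[a - 1]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
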