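"""Shared fixtures: configs and synthetic sessions.

Expensive session-scoped fixtures are generated once and reused across
test modules; they are deterministic (fixed seeds) so the suite is
reproducible run to run.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitphase import SessionConfig
from gaitphase import synth
from gaitphase.motion import BodySpeedSeries


@pytest.fixture(scope="session")
def config() -> SessionConfig:
    return SessionConfig(rng_seed=0)


@pytest.fixture(scope="session")
def default_gait_session(config):
    """120 s default-parameter session: deterministic limb coupling."""
    pose, truth = synth.generate_gait(synth.GaitParams(), 120.0, seed=1, config=config)
    return pose, truth


@pytest.fixture(scope="session")
def walking_truth(config):
    """Near-continuous walking: dense valid-phase coverage for spike tests."""
    params = synth.GaitParams(
        bout_rate_per_min=6.0, bout_duration_mean_s=60.0, bout_duration_sd_s=1.0
    )
    pose, truth = synth.generate_gait(params, 320.0, seed=5, config=config)
    return pose, truth


@pytest.fixture(scope="session")
def walking_phase_lr(walking_truth, config):
    _, truth = walking_truth
    return synth.truth_phase_series(truth, "lr", config)


def make_speed_series(speed: np.ndarray, fs: float = 80.0) -> BodySpeedSeries:
    """Wrap a bare speed trace for bout-detection tests."""
    speed = np.asarray(speed, dtype=float)
    n = speed.size
    return BodySpeedSeries(
        speed_mm_s=speed,
        centroid_mm=np.zeros((n + 1, 2)),
        heading_deg=np.zeros(n),
        frame_rate_hz=fs,
        valid=np.ones(n, dtype=bool),
    )


def reference_bout_scan(
    v: np.ndarray, fs: float, high: float = 50.0, low: float = 20.0, min_s: float = 0.3
) -> list[tuple[int, int]]:
    """Independent brute-force bout detector used as an oracle.

    Literal reading of the rule: suprathreshold (> high) runs lasting
    at least ``min_s`` are kept, each extended backward/forward through
    samples >= low, then overlapping/touching bouts merged.
    """
    n = v.size
    runs = []
    i = 0
    while i < n:
        if v[i] > high:
            j = i
            while j + 1 < n and v[j + 1] > high:
                j += 1
            if (j - i + 1) / fs >= min_s:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        while a > 0 and v[a - 1] >= low:
            a -= 1
        while b < n - 1 and v[b + 1] >= low:
            b += 1
        if merged and a <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(b, merged[-1][1]))
        else:
            merged.append((a, b))
    return merged
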