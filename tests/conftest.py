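"""Shared fixtures: small ground-truthed synthetic recordings.

Simulations are session-scoped; tests that need a variant build their own.
"""

from __future__ import annotations

import numpy as np
import pytest

from hemopulse import (
    FlowSimParams,
    HeartSimParams,
    RectROI,
    detect_beats,
    extract_trace,
    simulate_flow,
    simulate_heart,
)


def full_roi(stack) -> RectROI:
    h, w = stack.frame_shape
    return RectROI(0, 0, w, h)


@pytest.fixture(scope="session")
def heart_600():
    """Metronomic 600 bpm heart, 10 s at 200 fps (grid-aligned beat period)."""
    stack, truth = simulate_heart(HeartSimParams(rate_bpm=600.0, seed=11))
    return stack, truth


@pytest.fixture(scope="session")
def heart_600_trace(heart_600):
    stack, truth = heart_600
    return extract_trace(stack, full_roi(stack)), truth


@pytest.fixture(scope="session")
def heart_600_beats(heart_600_trace):
    trace, truth = heart_600_trace
    return detect_beats(trace), truth


@pytest.fixture(scope="session")
def heart_jittered():
    """600 bpm with 10 ms beat-to-beat jitter — irregular rhythm."""
    stack, truth = simulate_heart(
        HeartSimParams(rate_bpm=600.0, interval_sd_s=0.01, seed=12)
    )
    return stack, truth


@pytest.fixture(scope="session")
def flow_pulsatile():
    """20-cell corridor, mean 1000 um/s, fully pulsatile (speed swings 0-2000)."""
    stack, truth = simulate_flow(
        FlowSimParams(n_cells=20, mean_speed_um_s=1000.0, pulsatility_frac=1.0, seed=13)
    )
    return stack, truth


@pytest.fixture(scope="session")
def flow_steady_small():
    """5-cell steady corridor, short record — quick tracking fixture."""
    stack, truth = simulate_flow(
        FlowSimParams(
            n_cells=5, mean_speed_um_s=800.0, pulsatility_frac=0.0, duration_s=0.4, seed=14
        )
    )
    return stack, truth
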