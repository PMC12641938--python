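"""Shared fixtures: geometry, study profiles, small generated sessions."""

from __future__ import annotations

import numpy as np
import pytest

import surgaze as sg
from surgaze import events as ev


@pytest.fixture(scope="session")
def geometry() -> sg.ViewGeometry:
    return sg.ViewGeometry()


@pytest.fixture(scope="session")
def surfaces(geometry):
    return sg.generate_surfaces(geometry)


@pytest.fixture(scope="session")
def attending():
    return sg.STUDY_PROFILES["attending"]


@pytest.fixture(scope="session")
def pgy2():
    return sg.STUDY_PROFILES["PGY2"]


@pytest.fixture(scope="session")
def short_session(attending, geometry, surfaces):
    """One 60 s attending session with its ground truth (shared, read-only)."""
    return sg.generate_session(attending, geometry, surfaces, 60.0, seed=11)


@pytest.fixture(scope="session")
def detected_short(short_session):
    stream, log = short_session
    filtered = ev.filter_by_confidence(stream, 0.6)
    return ev.detect_fixations(filtered), log


def make_stream(t, x, y, conf=None, rate=200.0) -> sg.GazeStream:
    t = np.asarray(t, dtype=float)
    if conf is None:
        conf = np.ones_like(t)
    return sg.GazeStream(
        t=t, x=np.asarray(x, float), y=np.asarray(y, float),
        confidence=np.asarray(conf, float), nominal_rate=rate,
    )


def stationary_stream(duration: float, x0=5.0, y0=5.0, rate=200.0) -> sg.GazeStream:
    """A noise-free stationary dwell spanning exactly `duration` seconds."""
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    return make_stream(t, np.full(n, x0), np.full(n, y0), rate=rate)
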