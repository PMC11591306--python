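"""Shared trajectory builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from circledraw.geometry import RawTrajectory


def make_circle(
    radius: float = 1.0,
    center: tuple[float, float] = (0.0, 0.0),
    n: int = 400,
    closed: bool = True,
    speed_profile=None,
    phase: float = 0.0,
) -> RawTrajectory:
    """A circle sampled at ``n`` points, optionally with nonuniform speed.

    ``speed_profile`` maps uniform parameter u in [0, 1] to a monotone
    warp w(u) in [0, 1]; the default is uniform speed.
    """
    u = np.linspace(0.0, 1.0, n, endpoint=closed)
    if speed_profile is not None:
        u = speed_profile(u)
    th = phase + 2.0 * np.pi * u
    return RawTrajectory(
        t=np.linspace(0.0, 2.0, n),
        x=center[0] + radius * np.cos(th),
        y=center[1] + radius * np.sin(th),
    )


def make_ellipse(
    a: float = 2.0,
    b: float = 1.0,
    center: tuple[float, float] = (0.0, 0.0),
    rotation: float = 0.0,
    n: int = 800,
) -> RawTrajectory:
    th = np.linspace(0.0, 2.0 * np.pi, n)
    ex, ey = a * np.cos(th), b * np.sin(th)
    c, s = np.cos(rotation), np.sin(rotation)
    return RawTrajectory(
        t=np.linspace(0.0, 2.0, n),
        x=center[0] + c * ex - s * ey,
        y=center[1] + s * ex + c * ey,
    )


def make_line(
    start: tuple[float, float] = (0.0, 0.0),
    end: tuple[float, float] = (10.0, 0.0),
    n: int = 50,
) -> RawTrajectory:
    u = np.linspace(0.0, 1.0, n)
    return RawTrajectory(
        t=u,
        x=start[0] + u * (end[0] - start[0]),
        y=start[1] + u * (end[1] - start[1]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
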