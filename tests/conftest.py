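"""Shared fixtures: small synthetic sessions and cohorts built at test time."""

import numpy as np
import pytest

from graphoscreen.sessions import RawSession


def make_session(n=240, rate=240.0, child="c0", tp="y1", game="copy_square",
                 idl="spontaneous", seed=0, duration=None):
    """A single synthetic stylus session with smooth sinusoidal channels."""
    rng = np.random.default_rng(seed)
    span = duration if duration is not None else (n - 1) / rate
    t = np.linspace(0.0, span, n)
    u = t / t[-1]
    samples = np.column_stack([
        t,
        400 + 50 * np.sin(2 * np.pi * 2.0 * u + rng.uniform(0, 2 * np.pi)),
        500 + 40 * np.sin(2 * np.pi * 3.0 * u + rng.uniform(0, 2 * np.pi)),
        1.5 + 0.3 * np.sin(2 * np.pi * 1.5 * u + rng.uniform(0, 2 * np.pi)),
        np.full(n, 0.9),
        np.full(n, 1.2),
    ])
    return RawSession(child, tp, game, 0, idl, samples, rate_hz=rate)


@pytest.fixture
def session():
    return make_session()


@pytest.fixture(scope="session")
def two_sinusoid_values():
    """60 samples at 50 Hz of sin(2*pi*2 t) + 0.5 sin(2*pi*5 t)."""
    t = np.arange(60) / 50.0
    return np.sin(2 * np.pi * 2 * t) + 0.5 * np.sin(2 * np.pi * 5 * t)


@pytest.fixture(scope="session")
def small_game_embeddings():
    """A small synthetic GameEmbeddings block: 4 units x 12 children, with
    the last 4 children carrying an extra high-frequency component."""
    from graphoscreen.embedding import GameEmbeddings

    rng = np.random.default_rng(42)
    U, C, s = 4, 12, 5
    at_risk = [2, 5, 8, 11]
    omega = rng.uniform(2 * np.pi * 1, 2 * np.pi * 5, (U, C, s))
    phi = rng.uniform(0, 2 * np.pi, (U, C, s))
    p = rng.normal(0, 0.5, (U, C, s))
    omega[:, at_risk, 0] = rng.uniform(2 * np.pi * 9, 2 * np.pi * 11, (U, 4))
    p[:, at_risk, 0] = 2.0
    units = [(f"id{k}", f) for k in range(2) for f in ("x", "y")]
    children = [f"c{i:02d}" for i in range(C)]
    return GameEmbeddings("y1", "copy_square", children, units, omega, phi, p,
                          np.zeros((U, C)))


@pytest.fixture(scope="session")
def small_labels():
    """Labels aligned with small_game_embeddings: children 2, 5, 8, 11 at risk."""
    y = np.zeros(12, dtype=bool)
    y[[2, 5, 8, 11]] = True
    return y
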