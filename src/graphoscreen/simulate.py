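"""Synthetic Play-Draw-Write cohort generator.

Real study data are not publicly distributable, so this module emulates the
acquisition protocol with the statistical structure the downstream pipeline
assumes: per child a latent graphomotor ability drives three noisy
handwriting z-scores (median < -2 => at-risk), and stroke channels are sums
of low-frequency sinusoids to which at-risk children add a high-frequency
"tremor" component — a frequency-coded class effect, since frequency-related
features are the most discriminative for handwriting difficulties.

Frequencies are expressed in cycles per (normalised) execution, so the class
structure survives the [0, 1] time rescaling of the preprocessing stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import ConfigurationWarning, InvalidInputError
from .sessions import (AT_RISK_THRESHOLD, COPY_MODES, LabelRecord, RawSession,
                       TunnelSpec, label_from_zscores)

#: base (healthy) frequency band, cycles per execution
BASE_FREQ_BAND = (1.0, 5.0)
#: tremor band added for at-risk children, cycles per execution
TREMOR_FREQ_BAND = (8.0, 12.0)

#: protocol tunnel geometries; the app's true values are unpublished, these
#: defaults realise the required 5 (square) / 8 (word) distinct A/W ratios
TUNNEL_SQUARE_IDS = (2.0, 3.0, 4.0, 5.0, 6.0)
TUNNEL_WORD_IDS = (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0)
_SQUARE_WIDTHS = (30.0, 40.0, 50.0)
_WORD_WIDTHS = (35.0, 45.0)


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_children: int = 60
    prevalence: float = 0.18
    effect_size: float = 2.0
    noise_sd: float = 0.05
    seed: int = 0
    time_points: tuple[str, ...] = ("y1",)
    samples_hz: float = 240.0
    #: sd of the per-exercise noise around the latent ability in the z-model
    z_noise_sd: float = 0.3
    #: execution duration range in seconds
    duration_range: tuple[float, float] = (1.5, 3.0)

    def __post_init__(self):
        if self.n_children < 4:
            raise InvalidInputError("n_children must be >= 4")
        if not 0 < self.prevalence < 1:
            raise InvalidInputError("prevalence must be in (0, 1)")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")


def tunnel_protocol(game: str) -> list[TunnelSpec]:
    """The 15 tunnel geometries presented by a tunnel game, covering 5
    (square) or 8 (word) distinct Indexes of Difficulty A/W."""
    if game == "tunnel_square":
        return [TunnelSpec(amplitude=idv * w, width=w)
                for idv in TUNNEL_SQUARE_IDS for w in _SQUARE_WIDTHS]
    if game == "tunnel_word":
        specs = []
        i = 0
        while len(specs) < 15:
            idv = TUNNEL_WORD_IDS[i % len(TUNNEL_WORD_IDS)]
            w = _WORD_WIDTHS[(i // len(TUNNEL_WORD_IDS)) % len(_WORD_WIDTHS)]
            specs.append(TunnelSpec(amplitude=idv * w, width=w))
            i += 1
        return specs
    raise InvalidInputError(f"{game!r} is not a tunnel game")


# ---------------------------------------------------------------------------
# z-score model and calibration

def _p_median_below(shift: float, prevalence: float, effect_size: float,
                    z_noise_sd: float, nodes=None) -> float:
    """P(median of the three z-scores < -2) under the latent-ability mixture.

    Given ability a, each z = a + shift + z_noise_sd * eps, so each falls
    below the threshold independently with probability F(a); the median of
    three does iff at least two do: F^2 (3 - 2F).  The ability is a mixture
    of N(0,1) (typical) and N(-effect_size,1) (intended at-risk), integrated
    with Gauss-Hermite quadrature.
    """
    if nodes is None:
        nodes = hermegauss(101)
    x, wq = nodes
    wq = wq / wq.sum()
    total = 0.0
    for weight, mean in ((1.0 - prevalence, 0.0), (prevalence, -effect_size)):
        a = mean + x
        F = norm.cdf((AT_RISK_THRESHOLD - shift - a) / z_noise_sd)
        total += weight * float(np.sum(wq * F * F * (3.0 - 2.0 * F)))
    return total


def calibrate_z_shift(prevalence: float, effect_size: float,
                      z_noise_sd: float) -> float:
    """Solve for the additive z-score shift that makes the expected at-risk
    fraction (median z < -2) equal the target prevalence.  Achieved
    prevalence is accurate to ~1e-3."""
    nodes = hermegauss(101)
    f = lambda s: _p_median_below(s, prevalence, effect_size, z_noise_sd, nodes) - prevalence
    return brentq(f, -30.0, 30.0, xtol=1e-10)


def generate_labels(config: CohortConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[list[LabelRecord], np.ndarray]:
    """Draw the latent abilities and z-scores for a cohort.

    Returns the label records and the latent ability vector (one entry per
    child, used to couple the signal model to the labels).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_children
    if n * config.prevalence < 1:
        warnings.warn("expected number of at-risk children is below 1",
                      ConfigurationWarning, stacklevel=2)
    intended = rng.random(n) < config.prevalence
    ability = rng.standard_normal(n) - config.effect_size * intended
    shift = calibrate_z_shift(config.prevalence, config.effect_size,
                              config.z_noise_sd)
    z = ability[:, None] + shift + config.z_noise_sd * rng.standard_normal((n, 3))
    labels = [label_from_zscores(f"c{i:05d}", *z[i]) for i in range(n)]
    return labels, ability


# ---------------------------------------------------------------------------
# signal model

def _channel(rng: np.random.Generator, u: np.ndarray, scale: float,
             at_risk: bool, effect_size: float, noise_sd: float) -> np.ndarray:
    """One stroke channel on the normalised phase grid u in [0, 1]."""
    k = rng.integers(2, 5)
    freqs = rng.uniform(*BASE_FREQ_BAND, k)
    amps = rng.uniform(0.5, 1.0, k) * scale
    phases = rng.uniform(0, 2 * np.pi, k)
    v = (amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * u
                                + phases[:, None])).sum(axis=0)
    if at_risk and effect_size > 0:
        f = rng.uniform(*TREMOR_FREQ_BAND)
        v += 0.3 * effect_size * scale * np.sin(
            2 * np.pi * f * u + rng.uniform(0, 2 * np.pi))
    return v + noise_sd * scale * rng.standard_normal(u.shape)


def _execution(rng: np.random.Generator, config: CohortConfig, child_id: str,
               time_point: str, game: str, execution_index: int,
               id_label: str, at_risk: bool) -> RawSession:
    duration = rng.uniform(*config.duration_range)
    n = max(int(round(duration * config.samples_hz)), 2)
    t = np.arange(n) / config.samples_hz
    u = t / t[-1]
    samples = np.empty((n, 6))
    samples[:, 0] = t
    pos_scale = rng.uniform(30.0, 80.0)
    samples[:, 1] = rng.uniform(100, 900) + _channel(
        rng, u, pos_scale, at_risk, config.effect_size, config.noise_sd)
    samples[:, 2] = rng.uniform(100, 900) + _channel(
        rng, u, pos_scale, at_risk, config.effect_size, config.noise_sd)
    samples[:, 3] = 1.5 + _channel(
        rng, u, 0.4, at_risk, config.effect_size, config.noise_sd)
    # inclination: essentially constant, as in real captures
    samples[:, 4] = rng.uniform(0.7, 1.1) + 0.005 * rng.standard_normal(n)
    samples[:, 5] = rng.uniform(0.0, 2 * np.pi) + 0.005 * rng.standard_normal(n)
    return RawSession(child_id, time_point, game, execution_index, id_label,
                      samples, rate_hz=config.samples_hz)


def generate_cohort(config: CohortConfig,
                    ) -> tuple[list[RawSession], list[LabelRecord]]:
    """Generate a full labelled cohort following the acquisition protocol:
    3 executions (copy modes) per Copy game, 15 tunnel executions in 5
    (square) / 8 (word) difficulty groups presented in per-child random
    order.  Deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    labels, _ = generate_labels(config, rng)
    sessions: list[RawSession] = []
    for lab in labels:
        for tp in config.time_points:
            for game in ("copy_square", "copy_sequence"):
                for i, mode in enumerate(COPY_MODES):
                    sessions.append(_execution(rng, config, lab.child_id, tp,
                                               game, i, mode, lab.at_risk))
            for game in ("tunnel_square", "tunnel_word"):
                specs = tunnel_protocol(game)
                order = rng.permutation(len(specs))
                for i, j in enumerate(order):
                    id_label = f"{specs[j].id_value:g}"
                    sessions.append(_execution(rng, config, lab.child_id, tp,
                                               game, i, id_label, lab.at_risk))
    return sessions, labels
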