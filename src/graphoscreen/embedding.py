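"""Learnable sinusoidal signal embedding (Time2Vec autoencoder).

Each cleaned channel is cut into overlapping windows and fed to a tiny
autoencoder: an affine encoder maps the window to one encoded scalar per
coordinate, a Time2Vec latent layer turns every encoded scalar tau into
s + 1 channels

    h_0 = omega_0 * tau + phi_0          (linear trend term)
    h_i = sin(omega_i * tau + phi_i)     (1 <= i <= s)

with shared learnable pulsations omega and phases phi, and an affine decoder
with one shared weight vector p recombines the channels to reconstruct every
coordinate.  After training, the triplet (omega_1..s, phi_1..s, p_1..s) is
the signal's compressed representation; the linear (i = 0) term is kept only
for reconstruction.

Training is plain full-batch Adam on the mean squared reconstruction error,
implemented in numpy with analytic gradients, and batched across many
independent fits (the pipeline trains one autoencoder per signal, which
amounts to thousands of tiny models per cohort).

The encoder bias is initialised to the window-local time grid and the
encoder weights to small noise, so the encoded scalar starts out as time
within the window and the learned pulsations are interpretable in radians
per unit of the series' (normalised) time axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ShortSeriesError, TrainingDivergenceError
from .sessions import CleanSeries

DEFAULT_S = 9
DEFAULT_WIN = 50
DEFAULT_HOP = 5
#: upper edge of the pulsation initialisation band, in cycles per unit time
OMEGA_INIT_MAX_CYCLES = 8.0


@dataclass
class TrainSpec:
    """Hyperparameters of one autoencoder fit."""

    epochs: int = 2000
    learning_rate: float = 1e-3
    seed: int = 0
    win: int = DEFAULT_WIN
    hop: int = DEFAULT_HOP
    s: int = DEFAULT_S
    #: time step between window coordinates; None = 1/win
    dt: float | None = None
    plateau_tol: float = 1e-8
    plateau_patience: int = 100

    def __post_init__(self):
        if self.win < 2 or self.hop < 1 or self.s < 1:
            raise ValueError("invalid TrainSpec: need win >= 2, hop >= 1, s >= 1")


@dataclass(frozen=True)
class Window:
    """A contiguous slice of one channel, ``win`` samples long."""

    values: np.ndarray
    start_index: int


@dataclass
class EmbeddedSignal:
    """The learned compressed representation of one channel.

    ``omega`` (pulsations, rad per unit time), ``phi`` (phases, rad) and
    ``p`` (decoder weights) are each of length s.  The linear Time2Vec term
    is retained only for reconstruction and is not part of the feature set.
    """

    omega: np.ndarray
    phi: np.ndarray
    p: np.ndarray
    linear_terms: tuple[float, float, float]
    recon_mse: float

    @property
    def s(self) -> int:
        return self.omega.shape[0]


def make_windows(values: np.ndarray, win: int = DEFAULT_WIN,
                 hop: int = DEFAULT_HOP) -> list[Window]:
    """Cut a channel into ordered, overlapping windows of ``win`` samples
    taken every ``hop`` samples."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < win:
        raise ShortSeriesError(f"series of length {n} cannot fill a window of {win}")
    starts = range(0, n - win + 1, hop)
    return [Window(values[s0:s0 + win].copy(), s0) for s0 in starts]


def time2vec(tau: float, omega: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Evaluate the Time2Vec map at scalar time ``tau``: element 0 is the
    linear term, elements 1..s are sines."""
    omega = np.asarray(omega, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.sin(omega * tau + phi)
    out[0] = omega[0] * tau + phi[0]
    return out


# ---------------------------------------------------------------------------
# batched trainer

#: zero-padding factor for the periodogram used to initialise pulsations
_SPECTRAL_PAD = 8


def _spectral_init(X: np.ndarray, dt: float, s: int,
                   rng: np.random.Generator):
    """Periodogram-based initial values for (omega, phi, p).

    ``X`` holds the windows (n_win, win) of one channel.  The pulsations
    start at the s strongest local peaks of the zero-padded Welch
    periodogram, the phases at the first window's spectral phase there, and
    the decoder weights at the corresponding amplitudes; slots beyond the
    available peaks fall back to random draws.  Gradient descent then
    refines from a point already inside the attraction basin of each
    frequency — random pulsations rarely converge across an oscillatory
    loss surface.
    """
    n, w = X.shape
    nfft = _SPECTRAL_PAD * w
    F = np.fft.rfft(X - X.mean(axis=1, keepdims=True), n=nfft, axis=1)
    mag = np.sqrt(np.mean(np.abs(F) ** 2, axis=0))
    freqs = np.fft.rfftfreq(nfft, dt)
    mag[0] = 0.0
    interior = mag[1:-1]
    is_peak = (interior > mag[:-2]) & (interior >= mag[2:])
    peak_idx = np.flatnonzero(is_peak) + 1
    peak_idx = peak_idx[np.argsort(-mag[peak_idx])][:s]

    omega = rng.uniform(0.0, 2 * np.pi * OMEGA_INIT_MAX_CYCLES, s)
    phi = rng.uniform(0.0, 2 * np.pi, s)
    p = rng.normal(0.0, 0.01, s)
    k = peak_idx.size
    if k:
        omega[:k] = 2 * np.pi * freqs[peak_idx]
        F0 = np.fft.rfft(X[0] - X[0].mean(), n=nfft)
        phi[:k] = np.angle(F0[peak_idx]) + np.pi / 2
        p[:k] = 2.0 * mag[peak_idx] / w
    return omega, phi, p


def _init_params(rng: np.random.Generator, X: np.ndarray, s: int, dt: float,
                 hop_dt: float):
    """Initialise one autoencoder.

    Pulsations/phases/weights come from :func:`_spectral_init`; the linear
    term starts inert.  The encoder bias starts as the window-local time
    grid and the encoder weights as the (min-norm ridge) linear map from
    window values to window start time, so the encoded scalar approximates
    absolute time from the first epoch.
    """
    n, w = X.shape
    omega = np.empty(s + 1)
    phi = np.empty(s + 1)
    p = np.empty(s + 1)
    omega[0] = rng.uniform(0.0, 1.0)
    phi[0] = rng.uniform(0.0, 2 * np.pi)
    p[0] = 0.0
    omega[1:], phi[1:], p[1:] = _spectral_init(X, dt, s, rng)

    t0 = np.arange(n) * hop_dt
    lam = 1e-6 * (np.trace(X.T @ X) / w + 1e-12)
    g = np.linalg.solve(X.T @ X + lam * np.eye(w), X.T @ t0)
    W = np.tile(g[:, None], (1, w)) + rng.normal(0.0, 1e-4, (w, w))
    c = np.arange(w) * dt
    d = np.full(w, X.mean())
    return [W, c, omega, phi, p, d]


def _fit_batch_chunk(X: np.ndarray, spec: TrainSpec, seeds: np.ndarray,
                     dt: float):
    """Train one autoencoder per leading element of ``X`` (B, n_win, win).

    Full-batch Adam; per-element plateau stopping; the best-loss snapshot
    of the extracted parameters is returned.  Internals run in float32 and
    flatten the (window, coordinate) axes — the tensors are small, so the
    epoch loop is memory-bound and batched 3-d matmuls keep it fast.
    """
    B, n, w = X.shape
    s = spec.s
    hop_dt = spec.hop * dt
    params = [np.stack(a).astype(np.float32) for a in zip(
        *(_init_params(np.random.default_rng(int(sd)), X[b], s, dt, hop_dt)
          for b, sd in enumerate(seeds)))]
    W, c, omega, phi, p, d = params
    Xf = X.astype(np.float32)
    Xflat = Xf.reshape(B, n * w)
    m = [np.zeros_like(a) for a in params]
    v = [np.zeros_like(a) for a in params]
    lr, b1, b2, eps = np.float32(spec.learning_rate), np.float32(0.9), \
        np.float32(0.999), np.float32(1e-8)
    one = np.float32(1.0)

    snap_omega, snap_phi, snap_p = omega.copy(), phi.copy(), p.copy()
    best = np.full(B, np.inf, dtype=np.float64)
    since = np.zeros(B, dtype=int)
    active = np.ones(B, dtype=bool)
    step = 0
    for epoch in range(spec.epochs + 1):
        E = (Xf @ W + c[:, None, :]).reshape(B, n * w)     # encoded scalars
        A = E[:, :, None] * omega[:, None, :] + phi[:, None, :]
        S = np.sin(A)
        S[:, :, 0] = A[:, :, 0]
        R = (S @ p[:, :, None])[:, :, 0] + np.tile(d, (1, n))
        D = R - Xflat
        loss = np.mean(D.astype(np.float64) ** 2, axis=1)
        if not np.all(np.isfinite(loss)):
            raise TrainingDivergenceError("non-finite reconstruction loss",
                                          epoch=epoch)
        improved = loss < best
        if improved.any():
            snap_omega[improved] = omega[improved]
            snap_phi[improved] = phi[improved]
            snap_p[improved] = p[improved]
        keep_going = loss < best - spec.plateau_tol
        best = np.minimum(best, loss)
        since = np.where(keep_going, 0, since + 1)
        active &= since < spec.plateau_patience
        if not active.any() or epoch == spec.epochs:
            break

        G = (np.float32(2.0 / (n * w)) * D) * active[:, None]
        C = np.cos(A)
        C[:, :, 0] = one
        gp = (G[:, None, :] @ S)[:, 0, :]
        GpC = G[:, :, None] * (p[:, None, :] * C)
        gomega = (E[:, None, :] @ GpC)[:, 0, :]
        gphi = GpC.sum(axis=1)
        dE = (G * (C @ (p * omega)[:, :, None])[:, :, 0]).reshape(B, n, w)
        gW = np.transpose(Xf, (0, 2, 1)) @ dE
        gc = dE.sum(axis=1)
        gd = G.reshape(B, n, w).sum(axis=1)
        grads = [gW, gc, gomega, gphi, gp, gd]

        step += 1
        corr1 = one - b1 ** step
        corr2 = one - b2 ** step
        for par, g, mi, vi in zip(params, grads, m, v):
            mi *= b1
            mi += (one - b1) * g
            vi *= b2
            vi += (one - b2) * g * g
            par -= lr * (mi / corr1) / (np.sqrt(vi / corr2) + eps)

    omega = snap_omega.astype(np.float64)
    phi = snap_phi.astype(np.float64)
    p = snap_p.astype(np.float64)
    # canonicalise the periodic components to non-negative pulsation:
    # p sin(w t + f) == -p sin(-w t - f)
    neg = omega[:, 1:] < 0
    omega[:, 1:] = np.where(neg, -omega[:, 1:], omega[:, 1:])
    phi[:, 1:] = np.where(neg, -phi[:, 1:], phi[:, 1:])
    p[:, 1:] = np.where(neg, -p[:, 1:], p[:, 1:])
    return omega, phi, p, best


def _fit_batched(X: np.ndarray, spec: TrainSpec, seeds: np.ndarray,
                 dt: float, chunk: int = 512):
    outs = []
    for lo in range(0, X.shape[0], chunk):
        outs.append(_fit_batch_chunk(X[lo:lo + chunk], spec,
                                     seeds[lo:lo + chunk], dt))
    omega, phi, p, loss = (np.concatenate(a) for a in zip(*outs))
    return omega, phi, p, loss


def _embedded_from_arrays(omega, phi, p, mse) -> EmbeddedSignal:
    return EmbeddedSignal(omega=omega[1:].copy(), phi=phi[1:].copy(),
                          p=p[1:].copy(),
                          linear_terms=(float(omega[0]), float(phi[0]), float(p[0])),
                          recon_mse=float(mse))


def fit_autoencoder(windows: list[Window], spec: TrainSpec) -> EmbeddedSignal:
    """Fit one autoencoder on a window set and extract the sinusoid triplet."""
    if not windows:
        raise ShortSeriesError("no windows to fit")
    X = np.stack([w.values for w in windows])[None, ...]
    dt = spec.dt if spec.dt is not None else 1.0 / spec.win
    omega, phi, p, loss = _fit_batched(X, spec, np.array([spec.seed]), dt)
    return _embedded_from_arrays(omega[0], phi[0], p[0], loss[0])


class SineAutoencoder:
    """Model object for one channel's sinusoidal decomposition.

    Mirrors the usual model/fit/results pattern: construct from the raw
    channel values (windowing is handled internally), call :meth:`fit`.
    """

    def __init__(self, values: np.ndarray, spec: TrainSpec | None = None):
        self.spec = spec or TrainSpec()
        self.windows = make_windows(values, self.spec.win, self.spec.hop)
        self.values = np.asarray(values, dtype=float)

    def fit(self) -> "SineDecompositionResults":
        emb = fit_autoencoder(self.windows, self.spec)
        return SineDecompositionResults(self, emb)


class SineDecompositionResults:
    """Fitted parameters of a :class:`SineAutoencoder`."""

    def __init__(self, model: SineAutoencoder, embedding: EmbeddedSignal):
        self.model = model
        self.embedding = embedding

    @property
    def omega(self):
        return self.embedding.omega

    @property
    def phi(self):
        return self.embedding.phi

    @property
    def p(self):
        return self.embedding.p

    @property
    def recon_mse(self):
        return self.embedding.recon_mse

    def dominant_components(self, k: int = 2) -> np.ndarray:
        """Indices of the k components with the largest |decoder weight|."""
        return np.argsort(-np.abs(self.embedding.p))[:k]

    def summary(self) -> str:
        e = self.embedding
        lines = [
            "Sinusoidal decomposition".center(58),
            "=" * 58,
            f"components (s): {e.s:>4d}    windows: {len(self.model.windows):>4d}"
            f"    recon MSE: {e.recon_mse:.3e}",
            "-" * 58,
            f"{'i':>3} {'omega (rad/u)':>14} {'freq (cyc/u)':>13} "
            f"{'phi (rad)':>10} {'p':>10}",
        ]
        order = np.argsort(-np.abs(e.p))
        for i in order:
            lines.append(f"{i + 1:>3} {e.omega[i]:>14.4f} "
                         f"{e.omega[i] / (2 * np.pi):>13.4f} "
                         f"{e.phi[i] % (2 * np.pi):>10.4f} {e.p[i]:>10.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)


def embed_series(series: CleanSeries, spec: TrainSpec) -> dict[str, EmbeddedSignal]:
    """Fit one independent autoencoder per channel of a cleaned series."""
    dts = np.diff(series.t)
    dt = float(np.mean(dts)) if dts.size else 1.0 / spec.win
    out = {}
    for feature, values in series.features.items():
        windows = make_windows(values, spec.win, spec.hop)
        X = np.stack([w.values for w in windows])[None, ...]
        omega, phi, p, loss = _fit_batched(X, replace(spec, dt=dt),
                                           np.array([spec.seed]), dt)
        out[feature] = _embedded_from_arrays(omega[0], phi[0], p[0], loss[0])
    return out


# ---------------------------------------------------------------------------
# cohort-level embedding

@dataclass
class GameEmbeddings:
    """All embeddings for one (time-point, game): arrays indexed by
    [unit, child, component] where a unit is an (id_label, feature) pair."""

    time_point: str
    game: str
    children: list[str]
    units: list[tuple[str, str]]
    omega: np.ndarray
    phi: np.ndarray
    p: np.ndarray
    recon_mse: np.ndarray
    linear: np.ndarray = field(default=None)  # (U, C, 3) linear-term rows

    @property
    def s(self) -> int:
        return self.omega.shape[2]

    def signal(self, unit_idx: int, child_idx: int) -> EmbeddedSignal:
        lin = (tuple(self.linear[unit_idx, child_idx])
               if self.linear is not None else (0.0, 0.0, 0.0))
        return EmbeddedSignal(self.omega[unit_idx, child_idx].copy(),
                              self.phi[unit_idx, child_idx].copy(),
                              self.p[unit_idx, child_idx].copy(),
                              lin, float(self.recon_mse[unit_idx, child_idx]))


def embed_cohort(representatives: dict[tuple[str, str, str], dict[str, CleanSeries]],
                 spec: TrainSpec,
                 ) -> dict[tuple[str, str], GameEmbeddings]:
    """Embed every representative series of a preprocessed cohort.

    ``representatives`` maps (child_id, time_point, game) to its per-ID
    series (the output of :func:`preprocess.preprocess_sessions`).  All fits
    for one (time-point, game) are trained batched; each fit gets its own
    deterministic seed derived from ``spec.seed`` and its position.
    """
    by_group: dict[tuple[str, str], dict] = {}
    for (child, tp, game), per_id in representatives.items():
        by_group.setdefault((tp, game), {})[child] = per_id

    out = {}
    for (tp, game), per_child in sorted(by_group.items()):
        children = sorted(per_child)
        id_labels = sorted({idl for per_id in per_child.values() for idl in per_id})
        features = sorted(next(iter(per_child.values()))[id_labels[0]].features)
        units = [(idl, f) for idl in id_labels for f in features]

        rows, dts = [], []
        for idl, feat in units:
            for child in children:
                series = per_child[child][idl]
                ws = make_windows(series.features[feat], spec.win, spec.hop)
                rows.append(np.stack([w.values for w in ws]))
                dts.append(np.mean(np.diff(series.t)))
        X = np.stack(rows)
        dt = float(np.mean(dts))
        seeds = np.array([
            np.random.SeedSequence([spec.seed & 0x7FFFFFFF, i]).generate_state(1)[0]
            for i in range(X.shape[0])], dtype=np.uint64)
        omega, phi, p, loss = _fit_batched(X, spec, seeds, dt)

        U, C, s1 = len(units), len(children), spec.s + 1
        omega = omega.reshape(U, C, s1)
        phi = phi.reshape(U, C, s1)
        p = p.reshape(U, C, s1)
        loss = loss.reshape(U, C)
        out[(tp, game)] = GameEmbeddings(
            tp, game, children, units,
            omega[:, :, 1:].copy(), phi[:, :, 1:].copy(), p[:, :, 1:].copy(),
            loss, linear=np.stack([omega[:, :, 0], phi[:, :, 0], p[:, :, 0]], axis=-1))
    return out


def embeddings_to_frame(embs: dict[tuple[str, str], GameEmbeddings]):
    """Flatten cohort embeddings to a long table (component_index 0 marks
    the linear term)."""
    import pandas as pd

    rows = []
    for (tp, game), ge in sorted(embs.items()):
        for u, (idl, feat) in enumerate(ge.units):
            for c, child in enumerate(ge.children):
                lin = ge.linear[u, c]
                rows.append((child, tp, game, idl, feat, 0,
                             lin[0], lin[1], lin[2]))
                for i in range(ge.s):
                    rows.append((child, tp, game, idl, feat, i + 1,
                                 ge.omega[u, c, i], ge.phi[u, c, i], ge.p[u, c, i]))
    return pd.DataFrame(rows, columns=["child_id", "time_point", "game",
                                       "id_label", "feature",
                                       "component_index", "omega", "phi", "p"])


def frame_to_embeddings(df) -> dict[tuple[str, str], GameEmbeddings]:
    """Inverse of :func:`embeddings_to_frame`."""
    out = {}
    for (tp, game), g in df.groupby(["time_point", "game"], sort=True):
        children = sorted(g["child_id"].unique())
        units = sorted({(str(i), str(f))
                        for i, f in zip(g["id_label"], g["feature"])})
        s = int(g["component_index"].max())
        U, C = len(units), len(children)
        omega = np.zeros((U, C, s))
        phi = np.zeros((U, C, s))
        p = np.zeros((U, C, s))
        linear = np.zeros((U, C, 3))
        uix = {u: k for k, u in enumerate(units)}
        cix = {c: k for k, c in enumerate(children)}
        for r in g.itertuples(index=False):
            u = uix[(str(r.id_label), str(r.feature))]
            c = cix[r.child_id]
            i = int(r.component_index)
            if i == 0:
                linear[u, c] = (r.omega, r.phi, r.p)
            else:
                omega[u, c, i - 1] = r.omega
                phi[u, c, i - 1] = r.phi
                p[u, c, i - 1] = r.p
        out[(str(tp), str(game))] = GameEmbeddings(
            str(tp), str(game), children, units, omega, phi, p,
            np.full((U, C), np.nan), linear=linear)
    return out
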