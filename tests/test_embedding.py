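"""Sinusoidal-latent autoencoder: windowing, the Time2Vec map, frequency
recovery, and training invariants."""

import numpy as np
import pytest

from graphoscreen.embedding import (SineAutoencoder, TrainSpec, Window,
                                    embed_series, fit_autoencoder,
                                    make_windows, time2vec)
from graphoscreen.errors import ShortSeriesError
from graphoscreen.sessions import CleanSeries


def sinusoid_windows(freqs_amps, n=60, rate=50.0):
    t = np.arange(n) / rate
    v = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
    return np.asarray(v)


class TestMakeWindows:
    def test_single_window_boundary(self):
        assert len(make_windows(np.zeros(50), 50, 5)) == 1

    def test_count_and_start_indices(self):
        ws = make_windows(np.arange(100.0), 50, 5)
        assert len(ws) == 11
        assert [w.start_index for w in ws] == list(range(0, 51, 5))
        np.testing.assert_array_equal(ws[-1].values, np.arange(50.0, 100.0))

    def test_short_series_rejected(self):
        with pytest.raises(ShortSeriesError):
            make_windows(np.zeros(49), 50, 5)


class TestTime2Vec:
    def test_zero_time(self):
        omega = np.array([2.0, 1.0, 3.0])
        phi = np.array([0.5, 0.2, 0.9])
        out = time2vec(0.0, omega, phi)
        np.testing.assert_allclose(out, [0.5, np.sin(0.2), np.sin(0.9)])

    def test_all_zero_parameters(self):
        np.testing.assert_array_equal(
            time2vec(3.7, np.zeros(4), np.zeros(4)), np.zeros(4))

    def test_quarter_period_closed_form(self):
        s = 5
        omega = np.full(s + 1, np.pi / 2)
        phi = np.zeros(s + 1)
        out = time2vec(1.0, omega, phi)
        np.testing.assert_allclose(out[1:], 1.0)
        assert out[0] == pytest.approx(np.pi / 2)


class TestFitAutoencoder:
    def test_zero_signal_reconstructed_exactly(self):
        ws = make_windows(np.zeros(60), 50, 5)
        emb = fit_autoencoder(ws, TrainSpec(seed=0, epochs=200))
        assert emb.recon_mse < 1e-8

    def test_pure_sinusoid_frequency_recovery(self):
        v = sinusoid_windows([(3.0, 1.0)], n=100)
        res = SineAutoencoder(v, TrainSpec(seed=0, dt=1 / 50)).fit()
        i = res.dominant_components(1)[0]
        assert abs(res.omega[i] - 2 * np.pi * 3) < 0.5

    def test_two_sinusoid_reconstruction_and_recovery(self, two_sinusoid_values):
        res = SineAutoencoder(two_sinusoid_values,
                              TrainSpec(seed=0, dt=1 / 50)).fit()
        assert res.recon_mse <= 1e-3
        top = sorted(res.omega[res.dominant_components(2)])
        assert abs(top[0] - 2 * np.pi * 2) < 0.5
        assert abs(top[1] - 2 * np.pi * 5) < 0.5

    def test_seed_stability_of_reconstruction(self, two_sinusoid_values):
        mses = []
        for seed in range(5):
            res = SineAutoencoder(two_sinusoid_values,
                                  TrainSpec(seed=seed, dt=1 / 50,
                                            epochs=500)).fit()
            mses.append(max(res.recon_mse, 1e-12))
        assert max(mses) / min(mses) < 10.0 or max(mses) < 1e-4

    def test_more_components_never_much_worse(self, two_sinusoid_values):
        # a larger latent space can always represent the smaller fit; in
        # practice gradient noise perturbs the tiny residuals, so the check
        # allows either the multiplicative band or an absolute floor far
        # below the acceptable reconstruction error
        m = {}
        for s in (6, 12):
            res = SineAutoencoder(two_sinusoid_values,
                                  TrainSpec(seed=1, s=s, dt=1 / 50,
                                            epochs=800)).fit()
            m[s] = res.recon_mse
        assert m[12] <= max(m[6] * 1.1, 1e-4)

    def test_amplitude_equivariance(self):
        v = sinusoid_windows([(3.0, 1.0)], n=60)
        spec = TrainSpec(seed=2, dt=1 / 50)
        r1 = SineAutoencoder(v, spec).fit()
        r3 = SineAutoencoder(3.0 * v, spec).fit()
        p1 = np.abs(r1.p[r1.dominant_components(1)[0]])
        p3 = np.abs(r3.p[r3.dominant_components(1)[0]])
        assert p3 / p1 == pytest.approx(3.0, rel=0.2)


class TestEmbedSeries:
    def _series(self, n=101):
        t = np.linspace(0, 1, n)
        x = np.sin(2 * np.pi * 3 * t)
        return CleanSeries("c", "y1", "copy_square", "big", t,
                           {"x": x, "y": np.cos(2 * np.pi * 2 * t),
                            "pressure": x.copy()})

    def test_identical_channels_identical_embeddings(self):
        out = embed_series(self._series(), TrainSpec(seed=3, epochs=100))
        np.testing.assert_array_equal(out["x"].omega, out["pressure"].omega)
        np.testing.assert_array_equal(out["x"].p, out["pressure"].p)

    def test_component_count_is_s(self):
        out = embed_series(self._series(), TrainSpec(seed=0, s=9, epochs=50))
        for emb in out.values():
            assert emb.omega.shape == (9,)
            assert emb.phi.shape == (9,)
            assert emb.p.shape == (9,)

    def test_linear_term_excluded_from_features(self):
        out = embed_series(self._series(), TrainSpec(seed=0, epochs=50))
        emb = out["x"]
        assert len(emb.linear_terms) == 3
        assert emb.omega.shape[0] == emb.s  # only periodic components exposed


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Regression guard on the hand-rolled backward pass."""
        rng = np.random.default_rng(0)
        n, w, s = 3, 5, 2
        X = rng.normal(size=(1, n, w))
        W = rng.normal(size=(1, w, w)) * 0.1
        c = rng.normal(size=(1, w))
        omega = rng.uniform(0, 5, (1, s + 1))
        phi = rng.uniform(0, 2 * np.pi, (1, s + 1))
        p = rng.normal(size=(1, s + 1)) * 0.5
        d = rng.normal(size=(1, w)) * 0.1
        params = [W, c, omega, phi, p, d]

        def loss(params):
            W, c, omega, phi, p, d = params
            E = np.einsum("bnu,buw->bnw", X, W) + c[:, None, :]
            A = E[..., None] * omega[:, None, None, :] + phi[:, None, None, :]
            S = np.sin(A)
            S[..., 0] = A[..., 0]
            R = np.einsum("bnwk,bk->bnw", S, p) + d[:, None, :]
            return float(np.mean((R - X) ** 2, axis=(1, 2)).sum())

        # analytic gradients, mirroring the trainer's backward pass
        E = np.einsum("bnu,buw->bnw", X, W) + c[:, None, :]
        A = E[..., None] * omega[:, None, None, :] + phi[:, None, None, :]
        S = np.sin(A)
        S[..., 0] = A[..., 0]
        R = np.einsum("bnwk,bk->bnw", S, p) + d[:, None, :]
        G = (2.0 / (n * w)) * (R - X)
        C = np.cos(A)
        C[..., 0] = 1.0
        gp = np.einsum("bnw,bnwk->bk", G, S)
        GpC = G[..., None] * (p[:, None, None, :] * C)
        gomega = np.einsum("bnwk,bnw->bk", GpC, E)
        gphi = GpC.sum(axis=(1, 2))
        dE = G * np.einsum("bnwk,bk->bnw", C, p * omega)
        gW = np.einsum("bnu,bnw->buw", X, dE)
        gc = dE.sum(axis=1)
        gd = G.sum(axis=1)
        analytic = [gW, gc, gomega, gphi, gp, gd]

        eps = 1e-6
        for par, g in zip(params, analytic):
            it = np.nditer(par, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                par[i] += eps
                lp = loss(params)
                par[i] -= 2 * eps
                lm = loss(params)
                par[i] += eps
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(float(g[i]), rel=1e-4, abs=1e-7)
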