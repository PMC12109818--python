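"""Common spatial patterns: closed-form toy solution, invariants and
feature extraction."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from stentropy import (
    ExtractionConfig,
    csp_features,
    entropy_from_series,
    fit_csp,
    fit_multiclass,
    multiclass_features,
)
from stentropy.csp import CSPModel, load_model, save_model


def toy_epochs(var1, var2, n_epochs=4):
    """Deterministic 2-channel epochs with uncentered covariance
    exactly diag(var1, var2): orthogonal +/-1 patterns scaled."""
    a = np.sqrt(var1) * np.array([1.0, -1.0, 1.0, -1.0])
    b = np.sqrt(var2) * np.array([1.0, 1.0, -1.0, -1.0])
    return [np.vstack([a, b]) for _ in range(n_epochs)]


class TestFitCSP:
    def test_toy_closed_form_eigenvalues(self):
        """Class covariances diag(10,1) vs diag(1,10): the generalized
        eigenvalues are exactly {10/11, 1/11} and the filters align with
        the channel axes."""
        model = fit_csp(toy_epochs(10, 1), toy_epochs(1, 10), n_components=2)
        np.testing.assert_allclose(
            model.eigenvalues, [10 / 11, 1 / 11], atol=1e-12
        )
        first = model.filters[0] / np.linalg.norm(model.filters[0])
        last = model.filters[-1] / np.linalg.norm(model.filters[-1])
        assert abs(first[0]) > 0.999 and abs(last[1]) > 0.999

    def test_identical_distributions_give_half_eigenvalues(self, rng):
        eps_a = [rng.standard_normal((4, 200)) for _ in range(30)]
        eps_b = [rng.standard_normal((4, 200)) for _ in range(30)]
        model = fit_csp(eps_a, eps_b, n_components=4)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=0.1)

    def test_label_swap_symmetry(self, rng):
        eps_a = [rng.standard_normal((3, 100)) * np.array([[3.0], [1.0], [1.0]]) for _ in range(10)]
        eps_b = [rng.standard_normal((3, 100)) * np.array([[1.0], [1.0], [2.0]]) for _ in range(10)]
        m1 = fit_csp(eps_a, eps_b, n_components=2)
        m2 = fit_csp(eps_b, eps_a, n_components=2)
        np.testing.assert_allclose(
            m1.eigenvalues, 1.0 - m2.eigenvalues[::-1], atol=1e-10
        )
        np.testing.assert_allclose(
            np.abs(m1.filters), np.abs(m2.filters[::-1]), atol=1e-8
        )

    def test_simultaneous_diagonalization(self, rng):
        """Filters diagonalize both class covariances; matched diagonal
        pairs sum to 1 under composite normalization."""
        A = rng.standard_normal((5, 5))
        B = rng.standard_normal((5, 5))
        C_a = A @ A.T + 0.5 * np.eye(5)
        C_b = B @ B.T + 0.5 * np.eye(5)
        C_a /= np.trace(C_a)
        C_b /= np.trace(C_b)

        # epochs realizing those covariances exactly: L @ B with B B^T = T I
        def eps(C):
            L = np.linalg.cholesky(C)
            Q, _ = np.linalg.qr(rng.standard_normal((10, 10)))
            return [L @ (Q[:5] * np.sqrt(10))]

        model = fit_csp(eps(C_a), eps(C_b), n_components=4)
        W = model.filters
        Da = W @ C_a @ W.T
        Db = W @ C_b @ W.T
        off_a = Da - np.diag(np.diag(Da))
        off_b = Db - np.diag(np.diag(Db))
        assert np.abs(off_a).max() < 1e-8 and np.abs(off_b).max() < 1e-8
        np.testing.assert_allclose(np.diag(Da) + np.diag(Db), 1.0, atol=1e-8)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="channel mismatch"):
            fit_csp([rng.standard_normal((3, 50))], [rng.standard_normal((4, 50))], 2)

    def test_rank_deficient_composite_warns_and_regularizes(self, rng):
        row = rng.standard_normal(100)
        eps = [np.vstack([row, row, row])]  # rank-1 covariance
        with pytest.warns(UserWarning, match="ridge"):
            model = fit_csp(eps, eps, n_components=2)
        assert np.all(np.isfinite(model.filters))

    def test_invalid_n_components(self, rng):
        eps = [rng.standard_normal((4, 50))]
        with pytest.raises(ValueError, match="n_components"):
            fit_csp(eps, eps, n_components=3)


class TestCSPFeatures:
    def test_identity_filter_unit_variance_gives_zero(self):
        model = CSPModel(
            filters=np.array([[1.0]]), eigenvalues=np.array([0.5]), n_components=1
        )
        epoch = np.sign(np.sin(np.arange(100)))[None, :]  # uncentered var 1
        feats = csp_features(model, epoch)
        assert feats[0] == pytest.approx(0.0, abs=1e-12)

    def test_class_a_epoch_loads_on_first_filter(self):
        model = fit_csp(toy_epochs(10, 1), toy_epochs(1, 10), n_components=2)
        feats = csp_features(model, toy_epochs(10, 1)[0])
        assert feats[0] > feats[1]

    def test_softmax_normalization(self, rng):
        eps = [rng.standard_normal((6, 80)) for _ in range(8)]
        model = fit_csp(eps[:4], eps[4:], n_components=4)
        feats = csp_features(model, eps[0])
        assert np.exp(feats).sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_epoch_rejected(self):
        model = CSPModel(
            filters=np.eye(2), eigenvalues=np.array([0.6, 0.4]), n_components=2
        )
        with pytest.raises(ValueError, match="degenerate"):
            csp_features(model, np.zeros((2, 50)))


class TestMulticlass:
    def test_two_classes_reduce_to_single_binary_model(self, rng):
        data = {
            1: [rng.standard_normal((4, 60)) for _ in range(5)],
            0: [rng.standard_normal((4, 60)) for _ in range(5)],
        }
        models = fit_multiclass(data, n_components=4)
        assert len(models) == 1
        assert models[0].class_pair == (1, 0)

    def test_three_class_feature_length(self, rng):
        data = {
            lab: [rng.standard_normal((10, 60)) for _ in range(5)]
            for lab in (1, 0, -1)
        }
        models = fit_multiclass(data, n_components=8)
        assert len(models) == 3
        feats = multiclass_features(models, data[1][0])
        assert feats.shape == (24,)

    def test_small_class_rejected(self, rng):
        data = {
            1: [rng.standard_normal((4, 60))],
            0: [rng.standard_normal((4, 60)) for _ in range(3)],
        }
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_multiclass(data, n_components=4)


class TestOnSyntheticEEG:
    def test_ovr_eigenvalues_exceed_half_on_effect_data(
        self, small_band_series, small_labels
    ):
        ent = entropy_from_series(small_band_series["gamma"], 20)
        data = {lab: ent[small_labels == lab] for lab in (1, 0, -1)}
        models = fit_multiclass(data, n_components=8)
        for m in models:
            assert m.eigenvalues[0] > 0.5

    def test_first_feature_auc_on_gamma_effect(
        self, small_band_series, small_labels
    ):
        """Gamma-band effect_gain=6 data: the first CSP feature of the
        positive-vs-negative model separates the classes (AUC > 0.9)."""
        ent = entropy_from_series(small_band_series["gamma"], 20)
        mask = np.isin(small_labels, [1, -1])
        ent, y = ent[mask], small_labels[mask]
        model = fit_csp(ent[y == 1], ent[y == -1], n_components=8)
        scores = np.array([csp_features(model, e)[0] for e in ent])
        auc = roc_auc_score((y == 1).astype(int), scores)
        assert max(auc, 1 - auc) > 0.9


def test_model_roundtrip(tmp_path, rng):
    eps = [rng.standard_normal((4, 60)) for _ in range(6)]
    model = fit_csp(eps[:3], eps[3:], n_components=4, class_pair=(1, -1), band="gamma")
    path = tmp_path / "model.npz"
    save_model(model, path)
    loaded = load_model(path)
    np.testing.assert_array_equal(loaded.filters, model.filters)
    np.testing.assert_array_equal(loaded.eigenvalues, model.eigenvalues)
    assert loaded.class_pair == (1, -1)
    assert loaded.band == "gamma"
    assert loaded.n_components == 4
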