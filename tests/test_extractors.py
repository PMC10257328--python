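"""Neural extractors and classical feature selectors."""

import numpy as np
import pytest

from fpbow.encoding import encode_matrix
from fpbow.extractors import (
    ExtractorConfig,
    build_neural,
    extract,
    fit,
    fit_selector,
    sweep_learning_rates,
)
from fpbow.fingerprints import fingerprint_matrix
from fpbow.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="module")
def planted_tokens():
    """600 separable (noise-free) molecules as token matrix + labels."""
    ds, _ = generate(SyntheticConfig(n_molecules=600, active_fraction=0.3, seed=2))
    tokens = encode_matrix(fingerprint_matrix(ds.smiles))
    return tokens, ds.labels


class TestBuild:
    def test_cnn_forward_contract(self, rng):
        cfg = ExtractorConfig(kind="cnn", seed=0)
        net = build_neural(cfg, "tokens", l_pad=300, vocab_size=2049)
        x = rng.integers(0, 2049, size=(4, 300))
        probs = net.predict_proba(x)
        assert probs.shape == (4,) and ((probs >= 0) & (probs <= 1)).all()

    def test_bilstm_has_more_parameters_than_lstm(self):
        lstm = build_neural(ExtractorConfig(kind="lstm", seed=0), "tokens", l_pad=40, vocab_size=100)
        bilstm = build_neural(
            ExtractorConfig(kind="bilstm", seed=0), "tokens", l_pad=40, vocab_size=100
        )
        assert bilstm.n_params > lstm.n_params

    def test_recurrent_layer_cap(self):
        with pytest.raises(ValueError, match="maximum"):
            ExtractorConfig(kind="lstm", recurrent_layers=3)

    def test_two_recurrent_layers_allowed(self, rng):
        net = build_neural(
            ExtractorConfig(kind="lstm", recurrent_layers=2, seed=0),
            "tokens",
            l_pad=10,
            vocab_size=50,
        )
        assert net.predict_proba(rng.integers(0, 50, size=(3, 10))).shape == (3,)

    def test_recurrent_units_invalid_for_cnn(self):
        with pytest.raises(ValueError, match="recurrent_units"):
            ExtractorConfig(kind="cnn", recurrent_units=64)

    def test_vector_input_uses_same_conv_stack(self, rng):
        net = build_neural(ExtractorConfig(kind="cnn", seed=0), "vector", input_dim=100)
        assert net.predict_proba(rng.normal(size=(5, 100))).shape == (5,)

    def test_selector_kind_rejected(self):
        with pytest.raises(ValueError, match="not a neural"):
            build_neural(ExtractorConfig(kind="pca"), "vector", input_dim=10)


class TestFit:
    def test_recovers_planted_signal(self, planted_tokens):
        tokens, y = planted_tokens
        cfg = ExtractorConfig(kind="cnn", epochs=15, batch_size=20, seed=0)
        net = build_neural(cfg, "tokens", l_pad=tokens.l_pad, vocab_size=tokens.vocabulary_size)
        trained = fit(net, tokens, y, cfg)
        assert trained.history["accuracy"][-1] >= 0.95

    def test_zero_epochs_leaves_weights_untouched(self, planted_tokens):
        tokens, y = planted_tokens
        cfg = ExtractorConfig(kind="cnn", epochs=0, seed=0)
        net = build_neural(cfg, "tokens", l_pad=tokens.l_pad, vocab_size=tokens.vocabulary_size)
        before = net.head.w.copy()
        trained = fit(net, tokens, y, cfg)
        assert np.array_equal(trained.model.head.w, before)

    def test_non_binary_labels_rejected(self, planted_tokens):
        tokens, y = planted_tokens
        bad = y.copy()
        bad[0] = 2
        cfg = ExtractorConfig(kind="cnn", epochs=1, seed=0)
        net = build_neural(cfg, "tokens", l_pad=tokens.l_pad, vocab_size=tokens.vocabulary_size)
        with pytest.raises(ValueError, match="binary"):
            fit(net, tokens, bad, cfg)

    def test_seeded_refit_reproduces_features(self, planted_tokens):
        tokens, y = planted_tokens
        cfg = ExtractorConfig(kind="cnn", epochs=2, seed=11)

        def run():
            net = build_neural(cfg, "tokens", l_pad=tokens.l_pad, vocab_size=tokens.vocabulary_size)
            return fit(net, tokens, y, cfg).extract(tokens)

        assert np.array_equal(run(), run())


class TestExtract:
    @pytest.fixture(scope="class")
    def trained(self, planted_tokens):
        tokens, y = planted_tokens
        cfg = ExtractorConfig(kind="cnn", epochs=3, seed=1)
        net = build_neural(cfg, "tokens", l_pad=tokens.l_pad, vocab_size=tokens.vocabulary_size)
        return fit(net, tokens, y, cfg)

    def test_shape_is_penultimate_width(self, planted_tokens, trained):
        tokens, _ = planted_tokens
        feats = extract(trained, tokens)
        assert feats.shape == (len(tokens), trained.output_dim)
        assert trained.output_dim == trained.config.dense_sizes[-1]

    def test_identical_rows_give_identical_features(self, trained, planted_tokens):
        tokens, _ = planted_tokens
        dup = np.vstack([tokens.rows[:1], tokens.rows[:1]])
        feats = trained.model.features(dup)
        assert np.array_equal(feats[0], feats[1])

    def test_inference_is_bitwise_deterministic(self, trained, planted_tokens):
        tokens, _ = planted_tokens
        assert np.array_equal(extract(trained, tokens), extract(trained, tokens))

    def test_shape_mismatch_rejected(self, trained, rng):
        with pytest.raises(ValueError, match="length"):
            extract(trained, rng.integers(0, 10, size=(2, 5)))


class TestSelectors:
    def test_lda_projects_binary_to_one_dimension(self, rng):
        x = rng.normal(size=(50, 8))
        y = (x[:, 0] > 0).astype(int)
        sel = fit_selector("lda", x, y)
        assert sel.output_dim == 1 and sel.extract(x).shape == (50, 1)

    def test_pca_component_count_matches_eigenvalue_oracle(self, rng):
        # spectrum with 3 dominant directions covering > 90% variance
        scales = np.array([10.0, 8.0, 6.0, 0.5, 0.4, 0.3, 0.2, 0.1])
        x = rng.normal(size=(400, 8)) * scales
        sel = fit_selector("pca", x, None)
        # oracle: cumulative eigenvalue fraction of the sample covariance
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(x.T)))[::-1]
        cum = np.cumsum(eigvals) / eigvals.sum()
        k_oracle = int(np.searchsorted(cum, 0.9) + 1)
        assert sel.output_dim == k_oracle
        explained = sel.transform.explained_variance_ratio_.sum()
        assert explained >= 0.9

    def test_pca_retains_90_percent_variance(self, rng):
        x = rng.normal(size=(100, 12)) * np.linspace(3, 0.1, 12)
        sel = fit_selector("pca", x, None)
        assert sel.transform.explained_variance_ratio_.sum() >= 0.9

    def test_dta_keeps_fully_determining_feature(self, rng):
        x = rng.normal(size=(200, 10))
        y = (x[:, 4] > 0).astype(int)
        sel = fit_selector("dta", x, y)
        assert 4 in sel.transform
        assert sel.extract(x).shape[1] == sel.output_dim

    def test_single_class_labels_rejected(self, rng):
        x = rng.normal(size=(20, 4))
        with pytest.raises(ValueError, match="both classes"):
            fit_selector("lda", x, np.zeros(20, dtype=int))

    def test_pca_degenerate_on_constant_columns(self):
        with pytest.raises(ValueError, match="constant"):
            fit_selector("pca", np.ones((10, 3)), None)


def test_learning_rate_sweep_returns_lowest_loss(planted_tokens):
    tokens, y = planted_tokens
    cfg = ExtractorConfig(kind="cnn", epochs=2, batch_size=50, seed=0)

    def build():
        return build_neural(cfg, "tokens", l_pad=tokens.l_pad, vocab_size=tokens.vocabulary_size)

    best, results = sweep_learning_rates(build, tokens, y, cfg, rates=(0.00025, 0.001))
    assert set(results) == {0.00025, 0.001}
    assert results[best.config.learning_rate] == min(results.values())
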