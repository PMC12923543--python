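"""Classifier unit tests: tokenization, normalization, forward pass, loss,
metrics, and small-scale training behavior."""

import logging

import numpy as np
import pytest

from nanochop import simulate as S
from nanochop import model as M
from nanochop.io_fastq import ReadRecord
from nanochop.workflows import evaluate_on_reads
from conftest import make_record


class TestTokenize:
    def test_single_nucleotide_tokens_are_distinct(self):
        tok = M.tokenize(make_record(sequence="ACGTN"))
        assert len(tok.token_ids) == 5
        assert len(set(tok.token_ids.tolist())) == 5
        assert M.PAD_ID not in tok.token_ids

    def test_empty_sequence(self):
        tok = M.tokenize(make_record(sequence=""))
        assert tok.length == 0 and tok.token_ids.size == 0

    def test_over_long_read_is_excluded_with_warning(self, caplog):
        long_rec = make_record(read_id="toolong", sequence="A" * 32771)
        with pytest.raises(M.ReadTooLongError):
            M.tokenize(long_rec)
        ok = make_record(read_id="ok", sequence="ACGT")
        with caplog.at_level(logging.WARNING):
            kept, kept_idx = M.tokenize_reads([long_rec, ok])
        assert kept_idx == [1]
        assert "toolong" in caplog.text

    def test_at_limit_read_is_kept(self):
        tok = M.tokenize(make_record(sequence="A" * 32770))
        assert tok.length == 32770


class TestNormalizeQualities:
    @pytest.mark.parametrize(
        "quals, expected",
        [([10, 10, 10], [0, 0, 0]), ([0, 20], [-1, 1])],
    )
    def test_examples(self, quals, expected):
        assert np.allclose(M.normalize_qualities(quals), expected)

    def test_zero_mean_unit_sd(self, rng):
        q = rng.integers(0, 60, size=200)
        z = M.normalize_qualities(q).astype(np.float64)
        assert abs(z.mean()) < 1e-6 and abs(z.std() - 1.0) < 1e-6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            M.normalize_qualities([])


@pytest.fixture(scope="module")
def tiny_model():
    return M.AdapterClassifier(
        M.ModelConfig(embed_dim=8, quality_hidden_dim=8, backbone_layers=2,
                      kernel_width=3, seed=0)
    )


class TestForward:
    def test_probabilities_sum_to_one(self, tiny_model, rng):
        rec = make_record(sequence="ACGTN" * 20, quality=12)
        rec.qualities = rng.integers(0, 40, size=len(rec))
        track = M.forward(tiny_model, M.tokenize(rec), rec.qualities)
        assert track.probabilities.shape == (100, 2)
        assert np.allclose(track.probabilities.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(track.labels, track.probabilities[:, 0] > 0.5)

    def test_zero_logits_give_half_half(self, tiny_model):
        """With the head zeroed, softmax symmetry puts every class at 0.5."""
        model = M.AdapterClassifier(tiny_model.config)
        model.params["hw2"][:] = 0.0
        model.params["hb2"][:] = 0.0
        rec = make_record(sequence="ACGT")
        track = M.forward(model, M.tokenize(rec), rec.qualities)
        assert np.allclose(track.probabilities, 0.5, atol=1e-6)

    def test_logit_offset_controls_probability_ratio(self, tiny_model):
        """logits (z, z+c) -> adapter/nonadapter probability ratio e^{-c}."""
        model = M.AdapterClassifier(tiny_model.config)
        model.params["hw2"][:] = 0.0
        c = 1.7
        model.params["hb2"][:] = np.array([0.0, c], dtype=np.float32)
        rec = make_record(sequence="ACGT")
        track = M.forward(model, M.tokenize(rec), rec.qualities)
        ratios = track.probabilities[:, 0] / track.probabilities[:, 1]
        assert np.allclose(ratios, np.exp(-c), rtol=1e-5)

    def test_batching_invariance(self, tiny_model, rng):
        """Predicting two reads in one batch equals predicting them separately."""
        recs = []
        for i, n in enumerate((37, 81)):
            seq = "".join(rng.choice(list("ACGT"), size=n))
            recs.append(ReadRecord(f"r{i}", seq, rng.integers(0, 40, size=n)))
        batched = tiny_model.predict(recs)
        singles = [tiny_model.predict([r])[0] for r in recs]
        for b, s in zip(batched, singles):
            assert np.allclose(b.probabilities, s.probabilities, atol=1e-5)

    def test_length_mismatch_is_error(self, tiny_model):
        rec = make_record(sequence="ACGT")
        with pytest.raises(ValueError, match="mismatch"):
            M.forward(tiny_model, M.tokenize(rec), [10, 10])

    def test_quality_pathway_is_optional(self):
        """Ablated config has no quality parameters yet predicts fine."""
        cfg = M.ModelConfig(embed_dim=8, quality_hidden_dim=8, backbone_layers=1,
                            kernel_width=3, use_quality=False)
        model = M.AdapterClassifier(cfg)
        assert not any(k.startswith("q") for k in model.params)
        rec = make_record(sequence="ACGTACGT")
        track = M.forward(model, M.tokenize(rec), rec.qualities)
        assert track.probabilities.shape == (8, 2)


class TestLoss:
    def test_half_probabilities_give_ln2(self):
        probs = [np.full(10, 0.5)]
        labels = [np.zeros(10)]
        assert abs(M.loss(probs, labels) - np.log(2)) < 1e-9

    def test_perfect_predictions_give_negligible_loss(self):
        y = np.array([0, 1, 1, 0], dtype=float)
        assert M.loss([y], [y]) <= 1e-6

    def test_batch_mean_is_unweighted_over_reads(self):
        """Reads of different lengths contribute equally (per-read mean first)."""
        p_short = np.full(5, np.exp(-0.2))  # per-read BCE 0.2 with labels all 1
        p_long = np.full(500, np.exp(-0.4))  # per-read BCE 0.4
        total = M.loss([p_short, p_long], [np.ones(5), np.ones(500)])
        assert abs(total - 0.3) < 1e-9

    def test_accepts_two_column_probabilities(self):
        track = np.column_stack([np.full(4, 0.5), np.full(4, 0.5)])
        assert abs(M.loss([track], [np.ones(4)]) - np.log(2)) < 1e-9


class TestEvaluate:
    @pytest.mark.parametrize(
        "tp, fp, fn, expected",
        [
            (5, 0, 0, (1.0, 1.0, 1.0)),
            (1, 1, 1, (0.5, 0.5, 0.5)),
            (0, 0, 3, (0.0, 0.0, 0.0)),
        ],
    )
    def test_metric_arithmetic(self, tp, fp, fn, expected):
        report = M.EvalReport.from_counts(tp, fp, fn, tn=10)
        assert (report.precision, report.recall, report.f1) == expected

    def test_pooled_counts_match_sklearn(self, rng):
        """Independent cross-check against scikit-learn on random tracks."""
        from sklearn.metrics import f1_score, precision_score, recall_score

        preds = [rng.integers(0, 2, size=n) for n in (17, 60, 3)]
        truths = [rng.integers(0, 2, size=len(p)) for p in preds]
        report = M.evaluate(preds, truths)
        flat_p = np.concatenate(preds)
        flat_t = np.concatenate(truths)
        assert report.precision == pytest.approx(precision_score(flat_t, flat_p))
        assert report.recall == pytest.approx(recall_score(flat_t, flat_p))
        assert report.f1 == pytest.approx(f1_score(flat_t, flat_p))

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            M.evaluate([np.zeros(3)], [np.zeros(4)])


def test_analytic_gradients_match_finite_differences(rng):
    """Backprop agrees with central finite differences on a tiny network."""
    cfg = M.ModelConfig(embed_dim=6, quality_hidden_dim=5, backbone_layers=2,
                        kernel_width=3, dilation_base=2, seed=9)
    model = M.AdapterClassifier(cfg)
    B, T = 2, 13
    tokens = rng.integers(1, 6, size=(B, T))
    qz = rng.normal(size=(B, T)).astype(np.float32)
    mask = np.ones((B, T), dtype=np.float32)
    mask[1, 9:] = 0.0  # second read shorter: exercises padding masks
    y = rng.integers(0, 2, size=(B, T)).astype(np.float32)

    def batch_loss():
        probs, _ = model._forward_batch(tokens, qz, mask)
        p = np.clip(probs[..., 0].astype(np.float64), 1e-7, 1 - 1e-7)
        bce = -(y * np.log(p) + (1 - y) * np.log(1 - p)) * mask
        return float((bce.sum(1) / mask.sum(1)).mean())

    probs, cache = model._forward_batch(tokens, qz, mask, want_cache=True)
    w = (mask / mask.sum(1)[:, None] / B).astype(np.float32)
    dlogits = (probs - np.stack([y, 1 - y], -1)) * w[..., None]
    grads = model._backward_batch(cache, dlogits)

    eps = 1e-3
    checked = 0
    for key in ("emb", "qw1", "qw4", "c0W", "c1b", "hw1", "hw2", "hb2"):
        flat = model.params[key].reshape(-1)
        for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = batch_loss()
            flat[idx] = orig - eps
            down = batch_loss()
            flat[idx] = orig
            numeric = (up - down) / (2 * eps)
            analytic = grads[key].reshape(-1)[idx]
            assert analytic == pytest.approx(numeric, abs=2e-4), key
            checked += 1
    assert checked >= 30


def test_default_config_parameter_count_is_small():
    """The full-width model stays in the few-million range (single-digit M)."""
    model = M.AdapterClassifier(M.ModelConfig())
    assert 0 < model.n_parameters() < 10_000_000


def test_checkpoint_round_trip(tmp_path, tiny_model, rng):
    path = tmp_path / "model.npz"
    tiny_model.save(path)
    loaded = M.AdapterClassifier.load(path)
    assert loaded.config == tiny_model.config
    rec = make_record(sequence="ACGTACGTAC")
    a = M.forward(tiny_model, M.tokenize(rec), rec.qualities)
    b = M.forward(loaded, M.tokenize(rec), rec.qualities)
    assert np.allclose(a.probabilities, b.probabilities)


def _tiny_train_setup(n_reads, seed, **adapter_kwargs):
    bodies = S.BodyModel(length_distribution=("lognormal", {"median": 120, "sigma": 0.3}))
    adapters = S.AdapterModel(**adapter_kwargs)
    return S.generate_dataset(n_reads, seed=seed, bodies=bodies, adapters=adapters)


class TestTrain:
    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            M.train([], [], M.ModelConfig.small(), M.TrainConfig.desk_scale())

    def test_loss_descends_on_fixed_batch(self):
        splits = _tiny_train_setup(120, seed=21)
        cfg = M.ModelConfig(embed_dim=12, quality_hidden_dim=12, backbone_layers=2,
                            kernel_width=3, seed=21)
        tc = M.TrainConfig.desk_scale(max_epochs=2, val_interval_steps=10**6,
                                      shuffle_seed=21)
        model, history = M.train(splits.train, splits.val, cfg, tc)
        assert history[0]["train_loss"] > history[-1]["val_loss"]

    def test_training_is_deterministic(self):
        splits = _tiny_train_setup(100, seed=33)
        cfg = M.ModelConfig(embed_dim=8, quality_hidden_dim=8, backbone_layers=1,
                            kernel_width=3, seed=33)
        tc = M.TrainConfig.desk_scale(max_epochs=1, shuffle_seed=33)
        m1, h1 = M.train(splits.train, splits.val, cfg, tc)
        m2, h2 = M.train(splits.train, splits.val, cfg, tc)
        assert h1[-1]["val_f1"] == h2[-1]["val_f1"]
        for key in m1.params:
            assert np.array_equal(m1.params[key], m2.params[key])

    def test_recovers_clean_adapters(self):
        """Smoke-scale run: uncorrupted adapters are found with F1 >= 0.95."""
        splits = _tiny_train_setup(
            2000, seed=42, substitution_rate=0.0, indel_rate=0.0
        )
        model, history = M.train(
            splits.train,
            splits.val,
            M.ModelConfig.small(seed=42),
            M.TrainConfig.desk_scale(max_epochs=8, val_interval_steps=100,
                                     shuffle_seed=42),
        )
        report = evaluate_on_reads(model, splits.test)
        assert report.f1 >= 0.95

    def test_quality_block_helps_when_sequence_is_ambiguous(self):
        """On a quality-separable dataset the quality-aware model beats the
        sequence-only ablation (the direction the quality block exists for)."""
        bodies = S.BodyModel(
            length_distribution=("lognormal", {"median": 120, "sigma": 0.3})
        )
        splits = S.generate_dataset(
            1500, seed=77, bodies=bodies, adapters=S.ablation_adapter_model()
        )
        scores = {}
        for use_quality in (False, True):
            cfg = M.ModelConfig.small(seed=77)
            cfg.use_quality = use_quality
            model, _ = M.train(
                splits.train,
                splits.val,
                cfg,
                M.TrainConfig.desk_scale(max_epochs=2, val_interval_steps=100,
                                         shuffle_seed=77),
            )
            scores[use_quality] = evaluate_on_reads(model, splits.test).f1
        assert scores[True] > scores[False]


def test_history_tsv_written(tmp_path):
    history = [dict(step=10, epoch=0, train_loss=0.5, val_loss=0.4, val_f1=0.9, lr=1e-2)]
    path = tmp_path / "metrics.tsv"
    M.write_history_tsv(history, path)
    lines = path.read_text().strip().split("\n")
    assert lines[0].split("\t") == ["step", "epoch", "train_loss", "val_loss", "val_f1", "lr"]
    assert lines[1].startswith("10\t0\t0.5")
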