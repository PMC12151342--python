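import numpy as np
import pytest
from dataclasses import replace

from thermoplaid import simulate as ts
from thermoplaid.encoder import (
    DesignInputs,
    EncoderSpec,
    build_inputs,
    calibration_qq,
    circular_permutation_control,
    evaluate_roc_auc,
    train_encoder,
)
from thermoplaid.nnet import NetSpec
from thermoplaid.bouts import BoutEvent


def _const_temp_experiment(n_bins=200, temp=26.0, bouts=()):
    n_frames = n_bins * 10
    traj = ts.Trajectory(x=np.full(n_frames, 50.0), y=np.full(n_frames, 50.0),
                         heading=np.zeros(n_frames))
    return ts.Experiment(
        trajectory=traj, temperature=np.full(n_frames, temp), power=None,
        true_bouts=list(bouts), condition="plaid", exp_id="const",
    )


class TestBuildInputs:
    def test_no_bouts(self):
        exp = _const_temp_experiment()
        inp = build_inputs([exp], [[]])
        assert inp.labels.sum() == 0
        assert inp.bout_hist.sum() == 0
        np.testing.assert_allclose(inp.temp_hist, 26.0)

    def test_bout_end_bookkeeping(self):
        """A bout ending in bin k appears at the right lag of samples k+1..k+25."""
        k = 100
        bout = BoutEvent(k * 10 - 30, k * 10 + 5)  # ends in bin k
        exp = _const_temp_experiment(bouts=[bout])
        inp = build_inputs([exp], [[bout]])
        h = 25
        # sample for bin t sits at row t - h
        row = lambda t: inp.bout_hist[t - h]
        assert row(k + 1)[0] == 1.0 and row(k + 1)[1:].sum() == 0
        assert row(k + 25)[24] == 1.0 and row(k + 25)[:24].sum() == 0
        assert row(k + 26).sum() == 0
        # brute-force window oracle over all rows
        raster = np.zeros(200)
        raster[k] = 1
        for t in range(h, 200):
            np.testing.assert_array_equal(row(t), raster[t - h:t][::-1])

    def test_labels_are_causal(self):
        """The label bin never appears in its own history window."""
        k = 50
        bout = BoutEvent(k * 10 + 2, k * 10 + 40)  # starts and ends in bin k..k+4
        exp = _const_temp_experiment(bouts=[bout])
        inp = build_inputs([exp], [[bout]])
        lab_rows = np.flatnonzero(inp.labels)
        assert len(lab_rows) == 1
        assert inp.bout_hist[lab_rows[0]].sum() == 0  # its own end is not in the past

    def test_history_too_long_rejected(self):
        exp = _const_temp_experiment(n_bins=20)
        with pytest.raises(ValueError):
            build_inputs([exp], [[]])


class TestCircularPermutation:
    def _inputs(self):
        rng = np.random.default_rng(0)
        n = 300
        return DesignInputs(
            temp_hist=rng.normal(26, 0.5, (n, 25)),
            bout_hist=np.zeros((n, 25)),
            labels=(rng.uniform(size=n) < 0.1).astype(float),
            exp_ids=np.array(["a"] * 150 + ["b"] * 150, dtype=object),
        )

    def test_label_counts_conserved(self):
        inp = self._inputs()
        perm = circular_permutation_control(inp)
        assert perm.labels.sum() == inp.labels.sum()
        assert not np.array_equal(perm.labels, inp.labels)

    def test_double_half_rotation_is_identity(self):
        inp = self._inputs()
        twice = circular_permutation_control(
            circular_permutation_control(inp, 0.5), 0.5
        )
        np.testing.assert_array_equal(twice.labels, inp.labels)

    def test_zero_shift_rejected(self):
        with pytest.raises(ValueError):
            circular_permutation_control(self._inputs(), shift_fraction=1e-9)


class TestRocAuc:
    def _model_with_scores(self, scores, labels):
        class Fake:
            test_idx = np.arange(len(labels))

            def predict_logit(self, f):
                return np.asarray(scores, float)

        inp = DesignInputs(
            temp_hist=np.zeros((len(labels), 25)),
            bout_hist=np.zeros((len(labels), 25)),
            labels=np.asarray(labels, float),
            exp_ids=np.array(["e"] * len(labels), dtype=object),
        )
        return Fake(), inp

    def test_perfect_separation(self):
        m, inp = self._model_with_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert evaluate_roc_auc(m, inp) == 1.0

    def test_all_ties_is_chance(self):
        m, inp = self._model_with_scores([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert evaluate_roc_auc(m, inp) == 0.5

    def test_pairwise_enumeration(self):
        """{bout: .9, .4; non-bout: .8, .3} -> 3 of 4 concordant pairs."""
        m, inp = self._model_with_scores([0.9, 0.4, 0.8, 0.3], [1, 1, 0, 0])
        assert evaluate_roc_auc(m, inp) == 0.75

    def test_single_class_rejected(self):
        m, inp = self._model_with_scores([0.9, 0.4], [1, 1])
        with pytest.raises(ValueError):
            evaluate_roc_auc(m, inp)


class TestTraining:
    def test_determinism(self, small_inputs):
        a = train_encoder(small_inputs, EncoderSpec(net=NetSpec(epochs=2)), seed=5)
        b = train_encoder(small_inputs, EncoderSpec(net=NetSpec(epochs=2)), seed=5)
        f = small_inputs.features[:64]
        np.testing.assert_array_equal(a.predict_logit(f), b.predict_logit(f))
        np.testing.assert_array_equal(a.test_idx, b.test_idx)

    def test_single_class_rejected(self, small_inputs):
        bad = replace(small_inputs, labels=np.zeros_like(small_inputs.labels))
        with pytest.raises(ValueError):
            train_encoder(bad)

    def test_learnable_policy_beats_chance(self, small_inputs, quick_encoder):
        assert evaluate_roc_auc(quick_encoder, small_inputs) > 0.6

    def test_loss_decreases(self, quick_encoder):
        hist = np.asarray(quick_encoder.loss_history)
        assert hist[-1] < hist[0]

    def test_independent_labels_give_chance_auc(self, small_inputs):
        rng = np.random.default_rng(123)
        iid = replace(
            small_inputs,
            labels=(rng.uniform(size=small_inputs.labels.size)
                    < small_inputs.labels.mean()).astype(float),
        )
        m = train_encoder(iid, EncoderSpec(net=NetSpec(epochs=5)), seed=1)
        assert 0.4 < evaluate_roc_auc(m, iid) < 0.6

    def test_bayes_auc_upper_bounds_fit(self, small_plaid_set, small_inputs, quick_encoder, plaid_policy):
        """The encoder cannot beat the true generative policy's own AUC."""
        from sklearn.metrics import roc_auc_score

        feats = small_inputs.features
        true_logit = (
            plaid_policy.base_logit
            + (small_inputs.temp_hist - plaid_policy.temp_ref_c) @ plaid_policy.temp_kernel
            + small_inputs.bout_hist @ plaid_policy.bout_kernel
        )
        bayes = roc_auc_score(small_inputs.labels[quick_encoder.test_idx],
                              true_logit[quick_encoder.test_idx])
        fit = evaluate_roc_auc(quick_encoder, small_inputs)
        n_pos = small_inputs.labels[quick_encoder.test_idx].sum()
        se = 1.0 / np.sqrt(n_pos)  # conservative AUC standard error
        assert fit <= bayes + 2 * se


class TestCalibrationQQ:
    def test_constant_model_single_bin(self, small_inputs):
        class Const:
            trained = True

            def predict_proba(self, f):
                return np.full(f.shape[0], 0.25)

        centers, props, counts = calibration_qq(Const(), small_inputs, n_bins=5)
        occupied = counts > 0
        assert occupied.sum() == 1
        assert props[occupied][0] == pytest.approx(small_inputs.labels.mean())

    def test_oracle_probabilities_on_identity(self):
        """Binning by the true generative probability recovers it empirically."""
        rng = np.random.default_rng(7)
        n = 40_000
        p = rng.uniform(0.0, 0.3, n)
        labels = (rng.uniform(size=n) < p).astype(float)

        class Oracle:
            trained = True

            def predict_proba(self, f):
                return p

        inp = DesignInputs(
            temp_hist=np.zeros((n, 25)), bout_hist=np.zeros((n, 25)),
            labels=labels, exp_ids=np.array(["e"] * n, dtype=object),
        )
        centers, props, counts = calibration_qq(Oracle(), inp, n_bins=8)
        for c, q, m in zip(centers, props, counts):
            se = np.sqrt(c * (1 - c) / m)
            assert abs(q - c) < 4 * se + 1e-9

    def test_anticalibrated_model_on_antidiagonal(self):
        rng = np.random.default_rng(8)
        n = 40_000
        p = rng.uniform(0.2, 0.8, n)
        labels = (rng.uniform(size=n) < p).astype(float)

        class Anti:
            trained = True

            def predict_proba(self, f):
                return 1.0 - p

        inp = DesignInputs(
            temp_hist=np.zeros((n, 25)), bout_hist=np.zeros((n, 25)),
            labels=labels, exp_ids=np.array(["e"] * n, dtype=object),
        )
        centers, props, counts = calibration_qq(Anti(), inp, n_bins=6)
        ok = counts > 100
        np.testing.assert_allclose(props[ok], 1 - centers[ok], atol=0.05)
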