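"""Few-shot linear evaluation: selection, probing, F1, aggregation."""

import numpy as np
import pytest
from sklearn.metrics import f1_score

from segssl.evaluate import (
    EvalConfig,
    linear_probe,
    macro_f1,
    per_class_f1,
    run_trials,
    segment_split,
    select_few_shot,
    shot_sweep,
    windows_xy,
)
from segssl.model import HarModel, ModelSpec
from segssl.segments import WindowingConfig
from segssl.synthetic import generate_segments
from tests.conftest import tiny_synth_config

FAST_EVAL = EvalConfig(n_shots=10, n_trials=2, epochs=60, seed=0)


@pytest.fixture(scope="module")
def tiny_splits():
    segs = generate_segments(tiny_synth_config(segments_per_class=8))
    wc = WindowingConfig(window_length=64, stride=32)
    tr, va, te = segment_split(segs, rng=np.random.default_rng(1))
    X_tr, y_tr, classes = windows_xy(tr, wc)
    X_va, y_va, _ = windows_xy(va, wc, classes)
    X_te, y_te, _ = windows_xy(te, wc, classes)
    return (X_tr, y_tr), (X_va, y_va), (X_te, y_te)


@pytest.fixture(scope="module")
def probe_model():
    return HarModel(ModelSpec(channels=(8, 12, 16)), rng=0)


class TestSelectFewShot:
    def test_exact_count_per_class(self, rng):
        y = np.repeat(np.arange(6), 30)
        idx = select_few_shot(y, 10, rng)
        assert len(idx) == 60
        assert all((y[idx] == c).sum() == 10 for c in range(6))

    def test_small_class_taken_fully_with_warning(self, rng):
        y = np.array([0] * 3 + [1] * 20)
        with pytest.warns(UserWarning, match="taking all"):
            idx = select_few_shot(y, 10, rng)
        assert (y[idx] == 0).sum() == 3 and (y[idx] == 1).sum() == 10

    def test_seed_reproducibility(self):
        y = np.repeat(np.arange(4), 25)
        a = select_few_shot(y, 5, np.random.default_rng(9))
        b = select_few_shot(y, 5, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestMacroF1:
    def test_perfect_diagonal(self):
        assert macro_f1(np.diag([5, 3, 7])) == 1.0

    def test_hand_computed_confusion(self):
        conf = np.array([[2, 0], [1, 1]])
        np.testing.assert_allclose(
            per_class_f1(conf), [0.8, 2 / 3], atol=1e-4
        )
        assert macro_f1(conf) == pytest.approx(0.7333, abs=1e-4)

    def test_empty_class_contributes_zero(self):
        conf = np.array([[3, 0, 0], [0, 2, 0], [0, 0, 0]])
        assert per_class_f1(conf)[2] == 0.0
        assert macro_f1(conf) == pytest.approx(2 / 3)

    def test_matches_sklearn_on_random_predictions(self, rng):
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        from sklearn.metrics import confusion_matrix

        conf = confusion_matrix(y_true, y_pred, labels=np.arange(4))
        assert macro_f1(conf) == pytest.approx(
            f1_score(y_true, y_pred, average="macro"), abs=1e-12
        )

    def test_invariant_under_class_permutation(self, rng):
        conf = rng.integers(0, 20, size=(5, 5))
        perm = rng.permutation(5)
        assert macro_f1(conf[np.ix_(perm, perm)]) == pytest.approx(
            macro_f1(conf), abs=1e-12
        )

    def test_rejects_non_square(self):
        with pytest.raises(ValueError, match="square"):
            macro_f1(np.zeros((2, 3)))


class TestLinearProbe:
    def test_probe_never_mutates_encoder(self, probe_model, tiny_splits):
        tr, va, te = tiny_splits
        before = probe_model.state_arrays()
        linear_probe(probe_model, tr, va, te, FAST_EVAL)
        after = probe_model.state_arrays()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_separable_features_reach_perfect_f1(self, tiny_splits):
        """A probe on linearly separable activity classes must saturate."""

        class OneHotEncoder:
            spec = ModelSpec(channels=(8, 12, 16))

            def encode(self, X, train=False):
                from segssl.nn import Tensor

                # dominant-frequency energy is a linear giveaway here
                spec_mag = np.abs(np.fft.rfft(np.asarray(X), axis=1))
                return Tensor(spec_mag.mean(axis=2)[:, :16])

        tr, va, te = tiny_splits
        res = linear_probe(OneHotEncoder(), tr, va, te, FAST_EVAL)
        assert res.macro_f1 == 1.0

    def test_shuffled_labels_probe_near_chance(self, probe_model, tiny_splits):
        (X_tr, y_tr), va, (X_te, y_te) = tiny_splits
        rng = np.random.default_rng(0)
        res = linear_probe(
            probe_model,
            (X_tr, rng.permutation(y_tr)),
            (va[0], rng.permutation(va[1])),
            (X_te, rng.permutation(y_te)),
            FAST_EVAL,
        )
        C = len(np.unique(y_tr))
        assert res.macro_f1 < 1 / C + 0.25  # chance level plus MC slack

    def test_missing_training_class_errors(self, probe_model, tiny_splits):
        (X_tr, y_tr), va, te = tiny_splits
        keep = y_tr != 0
        with pytest.raises(ValueError, match="absent"):
            linear_probe(probe_model, (X_tr[keep], y_tr[keep]), va, te, FAST_EVAL)

    def test_confusion_consistency(self, probe_model, tiny_splits):
        tr, va, te = tiny_splits
        res = linear_probe(probe_model, tr, va, te, FAST_EVAL)
        assert res.confusion.sum() == len(te[1])
        assert res.macro_f1 == pytest.approx(macro_f1(res.confusion))


class TestRunTrials:
    def test_single_trial_mean_equals_trial(self, probe_model, tiny_splits):
        tr, va, te = tiny_splits
        cfg = EvalConfig(n_shots=5, n_trials=1, epochs=40, seed=3)
        summary = run_trials(probe_model, tr, va, te, cfg)
        assert summary.mean_macro_f1 == summary.trials[0].macro_f1
        assert summary.std_macro_f1 == 0.0

    def test_aggregation_matches_recomputation(self, probe_model, tiny_splits):
        tr, va, te = tiny_splits
        cfg = EvalConfig(n_shots=5, n_trials=3, epochs=40, seed=3)
        summary = run_trials(probe_model, tr, va, te, cfg)
        macros = [t.macro_f1 for t in summary.trials]
        assert summary.mean_macro_f1 == pytest.approx(np.mean(macros))
        assert summary.std_macro_f1 == pytest.approx(np.std(macros))
        per_class = np.stack([t.per_class_f1 for t in summary.trials])
        np.testing.assert_allclose(
            summary.mean_per_class_f1, per_class.mean(axis=0)
        )

    def test_trials_reseeded_independently(self, probe_model, tiny_splits):
        tr, va, te = tiny_splits
        cfg = EvalConfig(n_shots=5, n_trials=2, epochs=40, seed=3)
        s1 = run_trials(probe_model, tr, va, te, cfg)
        s2 = run_trials(probe_model, tr, va, te, cfg)
        assert [t.macro_f1 for t in s1.trials] == [t.macro_f1 for t in s2.trials]


def test_shot_sweep_reduces_to_run_trials(probe_model, tiny_splits):
    tr, va, te = tiny_splits
    cfg = EvalConfig(n_shots=99, n_trials=2, epochs=40, seed=1)
    table = shot_sweep(probe_model, tr, va, te, [5], cfg)
    assert set(table["shots"]) == {5}
    import dataclasses

    direct = run_trials(
        probe_model, tr, va, te, dataclasses.replace(cfg, n_shots=5)
    )
    np.testing.assert_allclose(
        sorted(table["macro_f1"]),
        sorted(t.macro_f1 for t in direct.trials),
    )


def test_segment_split_is_disjoint_and_stratified():
    segs = generate_segments(tiny_synth_config(segments_per_class=8))
    tr, va, te = segment_split(segs, rng=np.random.default_rng(0))
    ids = [s.segment_id for part in (tr, va, te) for s in part]
    assert len(ids) == len(set(ids)) == len(segs)
    for part in (tr, va, te):  # every class present in every split
        assert len({s.activity for s in part}) == 3


def test_cross_domain_transfer_to_halved_rate_runs(tiny_25hz_target):
    """Pretext at 50 Hz, target at 25 Hz: runs end-to-end, finite scores."""
    summary = _transfer(tiny_25hz_target, epochs=2)
    assert np.isfinite(summary.mean_macro_f1)
    assert 0.0 <= summary.mean_macro_f1 <= 1.0


def test_cross_domain_transfer_beats_chance_same_rate():
    """A transferred encoder probes above chance 1/C on an unseen cohort."""
    target = generate_segments(tiny_synth_config(seed=5, segments_per_class=6))
    summary = _transfer(target, epochs=8)
    assert summary.mean_macro_f1 > 1 / 3


@pytest.fixture(scope="module")
def tiny_25hz_target():
    return generate_segments(
        tiny_synth_config(
            seed=5,
            sampling_rate_hz=25.0,
            segments_per_class=6,
            segment_length_range=(120, 200),
        )
    )


def _transfer(target, epochs):
    from segssl.evaluate import cross_domain_eval
    from segssl.pretrain import PretrainConfig

    pretext = generate_segments(tiny_synth_config(seed=0, segments_per_class=6))
    return cross_domain_eval(
        pretext,
        target,
        "simclr_seg",
        WindowingConfig(window_length=48, stride=48),
        ModelSpec(channels=(8, 12, 16)),
        PretrainConfig(method="simclr_seg", epochs=epochs, batch_size=16, seed=0),
        EvalConfig(n_shots=5, n_trials=2, epochs=40, seed=0),
    )
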