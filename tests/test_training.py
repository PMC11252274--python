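"""Training protocol, splitting rules, evaluation reports, cross-validation."""

import numpy as np
import pytest

from vepdecode.models import EEGNetConfig, ModelHandle, build_eegnet
from vepdecode.preprocessing import EpochSet
from vepdecode.training import (TrainConfig, chance_level, cross_validate,
                                evaluate, grid_search, make_split,
                                merge_epochs, train_classifier)

N_CLASSES = 4
N_SAMPLES = 100
CFG = EEGNetConfig(f1_temporal_filters=8, depth_multiplier=2,
                   n_samples=N_SAMPLES, n_classes=N_CLASSES)


def make_epochs(n_per_class=12, seed=0, n_dropped=0, separable=True,
                session_id="s0"):
    """Small separable synthetic epochs: class-specific channel offsets."""
    rng = np.random.default_rng(seed)
    n = n_per_class * N_CLASSES
    labels = np.repeat(np.arange(N_CLASSES), n_per_class)
    data = rng.standard_normal((n, 8, N_SAMPLES)).astype(np.float32)
    if separable:
        for c in range(N_CLASSES):
            data[labels == c, c % 8, :] += 3.0
    retained = np.ones(n, dtype=bool)
    retained[:n_dropped] = False
    return EpochSet(data=data, labels=labels, retained=retained,
                    session_id=session_id)


@pytest.fixture(scope="module")
def trained():
    train, val = make_epochs(seed=0), make_epochs(seed=1)
    handle = build_eegnet(CFG, seed=0)
    cfg = TrainConfig(epochs=10, batch_size=16, max_lr=5e-3, seed=0)
    handle, history = train_classifier(handle, train, val, cfg)
    return handle, history, val


def test_training_reduces_loss_and_learns_separable_data(trained):
    _, history, _ = trained
    assert history.train_loss[-1] < history.train_loss[0]
    assert history.train_acc[-1] > 0.8


def test_history_records_lr_and_best_epoch(trained):
    _, history, _ = trained
    assert len(history.lr) == 10
    assert history.lr[-1] < history.lr[0]            # one-cycle annealed
    assert 0 <= history.best_epoch < 10


def test_same_seed_same_data_identical_weights():
    train, val = make_epochs(seed=0), make_epochs(seed=1)
    finals = []
    for _ in range(2):
        handle = build_eegnet(CFG, seed=0)
        handle, _ = train_classifier(
            handle, train, val, TrainConfig(epochs=2, batch_size=16, seed=3))
        finals.append(handle.network.state_dict())
    for k in finals[0]:
        np.testing.assert_array_equal(finals[0][k], finals[1][k])


def test_empty_split_rejected():
    empty = make_epochs(n_per_class=1)
    empty.retained[:] = False
    handle = build_eegnet(CFG)
    with pytest.raises(ValueError):
        train_classifier(handle, empty, None, TrainConfig(epochs=1))


class TestSplit:
    def test_fewest_missing_trials_wins_test_slot(self):
        recs = [make_epochs(n_dropped=5, session_id="a"),
                make_epochs(n_dropped=0, session_id="b"),
                make_epochs(n_dropped=2, session_id="c")]
        plan = make_split(recs)
        assert plan.test_idx == 1
        assert plan.val_idx == 2
        assert plan.train_idx == [0]

    def test_tie_broken_by_lowest_session_index(self):
        recs = [make_epochs(n_dropped=1), make_epochs(n_dropped=1),
                make_epochs(n_dropped=1), make_epochs(n_dropped=1)]
        plan = make_split(recs)
        assert plan.test_idx == 0 and plan.val_idx == 1
        assert plan.train_idx == [2, 3]

    def test_sets_pairwise_disjoint(self):
        recs = [make_epochs(n_dropped=k) for k in (3, 1, 4, 0, 2)]
        plan = make_split(recs)
        ids = plan.train_idx + [plan.val_idx, plan.test_idx]
        assert len(set(ids)) == len(recs)

    def test_fewer_than_three_recordings_rejected(self):
        with pytest.raises(ValueError):
            make_split([make_epochs(), make_epochs()])


class TestEvaluate:
    def test_uniform_random_predictor_sits_at_chance(self):
        """A random scorer on a balanced 20-class set: expected accuracy 5%."""
        assert chance_level(20) == pytest.approx(0.05)
        rng = np.random.default_rng(0)
        n = 20000
        labels = np.repeat(np.arange(20), n // 20)
        preds = rng.integers(0, 20, n)
        acc = (preds == labels).mean()
        # 5 sigma binomial band around 5%
        assert abs(acc - 0.05) < 5 * np.sqrt(0.05 * 0.95 / n)

    def test_perfect_predictor_diagonal_confusion(self):
        epochs = make_epochs(seed=5)

        class Perfect(ModelHandle):
            def predict(self, data):
                return epochs.retained_labels()
        handle = Perfect(build_eegnet(CFG).network, CFG, "eegnet")
        report = evaluate(handle, epochs, n_classes=N_CLASSES)
        assert report.accuracy == 1.0
        assert (report.confusion == np.diag(report.confusion.diagonal())).all()

    def test_confusion_row_sums_equal_class_counts(self, trained):
        handle, _, val = trained
        report = evaluate(handle, val, n_classes=N_CLASSES)
        counts = np.bincount(val.retained_labels(), minlength=N_CLASSES)
        np.testing.assert_array_equal(report.confusion.sum(axis=1), counts)
        assert report.accuracy == pytest.approx(
            report.confusion.trace() / report.confusion.sum())

    def test_empty_test_set_rejected(self, trained):
        handle, _, _ = trained
        empty = make_epochs(n_per_class=1)
        empty.retained[:] = False
        with pytest.raises(ValueError):
            evaluate(handle, empty)


class TestGridSearchAndCV:
    def test_single_config_grid_returns_it(self):
        recs = [make_epochs(seed=s, session_id=f"s{s}") for s in range(3)]
        plan = make_split(recs)
        best, final, table = grid_search(
            [CFG], recs, plan, TrainConfig(epochs=1, batch_size=32, seed=0))
        assert best is CFG
        assert len(table) == 1
        assert isinstance(final, ModelHandle)

    def test_tie_on_validation_prefers_fewer_parameters(self):
        small = EEGNetConfig(f1_temporal_filters=4, depth_multiplier=1,
                             n_samples=N_SAMPLES, n_classes=N_CLASSES)
        recs = [make_epochs(seed=s, separable=False, session_id=f"s{s}")
                for s in range(3)]
        # degenerate one-trial-per-class val set scores tie easily; instead
        # force the tie by monkeypatched evaluation: identical data/epochs=0
        # is impractical, so check the sort rule directly on the table
        plan = make_split(recs)
        _, _, table = grid_search(
            [CFG, small], recs, plan,
            TrainConfig(epochs=1, batch_size=32, seed=0))
        assert len(table) == 2
        tied = table.assign(val_accuracy=0.5)
        best = tied.sort_values(["val_accuracy", "n_parameters"],
                                ascending=[False, True]).iloc[0]
        assert best["n_parameters"] == min(table["n_parameters"])

    def test_cross_validation_holds_out_each_non_test_recording_once(self):
        recs = [make_epochs(seed=s, n_dropped=(0 if s == 0 else 1),
                            session_id=f"s{s}") for s in range(4)]
        accs, mean = cross_validate(
            TrainConfig(epochs=1, batch_size=32, seed=0), recs, config=CFG)
        assert len(accs) == 3                        # non-test recordings
        assert np.all((accs >= 0) & (accs <= 1))
        assert mean == pytest.approx(accs.mean())


def test_merge_epochs_concatenates_and_preserves_masks():
    a, b = make_epochs(seed=0, n_dropped=2), make_epochs(seed=1)
    merged = merge_epochs([a, b])
    assert merged.n_trials == a.n_trials + b.n_trials
    assert merged.n_dropped == 2
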