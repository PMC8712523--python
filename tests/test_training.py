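"""Protocol mechanics: augmentation, sampling, splits, early stopping, metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pifnet.architectures import build_model
from pifnet.training import (HYPERPARAMETER_GRID, SplitPlan, TrialRecord,
                             augment, convergence_report, evaluate,
                             make_splits, normalize, sample_hyperparameters,
                             train)


class TestNormalize:
    def test_scales_to_unit_max(self, rng):
        v = rng.random((4, 5, 6)) * 7.5
        out = normalize(v)
        assert out.max() == pytest.approx(1.0)
        assert np.allclose(out * v.max(), v)

    def test_idempotent(self, rng):
        v = normalize(rng.random((4, 4, 4)))
        assert np.allclose(normalize(v), v)

    def test_constant_volume_becomes_ones(self):
        assert np.all(normalize(np.full((3, 3, 3), 2.5)) == 1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            normalize(np.zeros((3, 3, 3)))


class TestAugment:
    def test_sagittal_flip_is_involution(self, rng):
        v = rng.random((6, 7, 6))
        assert np.array_equal(v[::-1][::-1], v)

    def test_pif_family_never_flips(self, rng):
        """PIF patches must see the same content every iteration, so the
        sagittally asymmetric marker may never be mirrored."""
        v = np.zeros((8, 8, 8))
        v[0, :, :] = 1.0  # marker on one sagittal extreme
        flips = 0
        for _ in range(500):
            out = augment(v, "pif", rng, max_translation=0)
            flips += int(out[-1].sum() > out[0].sum())
        assert flips == 0
        flips_base = sum(
            int(augment(v, "baseline", rng, max_translation=0)[-1].sum()
                > 0.5) for _ in range(500))
        assert flips_base > 100  # baseline does flip about half the time

    def test_translation_round_trip_zero_fills_border(self, rng):
        from pifnet.training import _translate

        v = rng.random((6, 6, 6))
        t = 2
        back = _translate(_translate(v, (t, 0, 0)), (-t, 0, 0))
        assert np.allclose(back[: 6 - t], v[: 6 - t])
        assert np.all(back[6 - t:] == 0)

    def test_translation_bounded(self, rng):
        v = np.zeros((8, 8, 8))
        v[4, 4, 4] = 1.0
        for _ in range(50):
            out = augment(v, "pif", rng, max_translation=2)
            pos = np.argwhere(out == 1.0)
            assert len(pos) == 1 and np.abs(pos[0] - 4).max() <= 2


class TestSampleHyperparameters:
    def test_architecture_constraint_over_5_draws(self):
        for seed in range(25):
            draws = sample_hyperparameters(np.random.default_rng(seed), 5)
            archs = [d["architecture"] for d in draws]
            assert archs.count("A") >= 2 and archs.count("B") >= 2

    def test_all_values_from_grid(self, rng):
        for d in sample_hyperparameters(rng, 5):
            assert d["architecture"] in HYPERPARAMETER_GRID["architecture"]
            assert d["learning_rate"] in HYPERPARAMETER_GRID["learning_rate"]
            assert d["batch_size"] in HYPERPARAMETER_GRID["batch_size"]
            assert d["patience"] in HYPERPARAMETER_GRID["patience"]

    def test_seeded_determinism(self):
        a = sample_hyperparameters(np.random.default_rng(3), 5)
        b = sample_hyperparameters(np.random.default_rng(3), 5)
        assert a == b

    def test_too_few_draws_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            sample_hyperparameters(rng, 3)


class TestMakeSplits:
    def test_singleton_subjects_exact_fractions(self, rng):
        ids = [f"s{i}" for i in range(100)]
        plan = SplitPlan(fractions=(0.64, 0.16, 0.20), n_repetitions=3)
        for tr, va, te in make_splits(ids, plan, rng):
            assert (len(tr), len(va), len(te)) == (64, 16, 20)

    @pytest.mark.parametrize("fractions", [
        (0.64, 0.16, 0.20), (0.72, 0.10, 0.18), (0.765, 0.085, 0.15)])
    def test_protocol_fraction_sets_supported(self, rng, fractions):
        ids = [f"s{i}" for i in range(200)]
        plan = SplitPlan(fractions=fractions, n_repetitions=2)
        for parts in make_splits(ids, plan, rng):
            sizes = [len(p) for p in parts]
            assert sum(sizes) == 200
            for size, frac in zip(sizes, fractions):
                assert abs(size - 200 * frac) <= 1

    def test_subjects_never_straddle_partitions(self, rng):
        # 30 subjects with 3 images each
        ids = [f"s{i}" for i in range(30) for _ in range(3)]
        plan = SplitPlan(fractions=(0.72, 0.10, 0.18), n_repetitions=5)
        for tr, va, te in make_splits(ids, plan, rng):
            subj = [set(ids[i] for i in part) for part in (tr, va, te)]
            assert not (subj[0] & subj[1] or subj[0] & subj[2]
                        or subj[1] & subj[2])

    @given(st.integers(0, 999))
    def test_partitions_disjoint_and_exhaustive(self, seed):
        ids = [f"s{i}" for i in range(17) for _ in range(2)]
        plan = SplitPlan(fractions=(0.6, 0.2, 0.2), n_repetitions=1)
        ((tr, va, te),) = make_splits(ids, plan, np.random.default_rng(seed))
        joined = np.concatenate([tr, va, te])
        assert len(joined) == len(ids)
        assert len(np.unique(joined)) == len(ids)

    def test_oversized_group_rejected(self, rng):
        ids = ["big"] * 30 + [f"s{i}" for i in range(10)]
        plan = SplitPlan(fractions=(0.5, 0.25, 0.25), n_repetitions=1)
        with pytest.raises(ValueError, match="group"):
            make_splits(ids, plan, rng)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SplitPlan(fractions=(0.5, 0.2, 0.2))


class TestEvaluate:
    def _perfect_model(self):
        class M:
            def predict_logits(self, x):
                # class 1 iff mean intensity above 0.5
                score = x.mean(axis=(1, 2, 3, 4))
                return np.stack([-score, score], axis=1)
        return M()

    def test_perfect_classifier_scores_100(self):
        vols = np.concatenate([np.full((5, 4, 4, 4), -1.0),
                               np.full((5, 4, 4, 4), 1.0)])
        labels = np.array([0] * 5 + [1] * 5)
        m = self._perfect_model()
        metrics = evaluate(m, vols, labels)
        assert all(metrics[k] == pytest.approx(100.0) for k in
                   ("auc_roc", "balanced_accuracy", "sensitivity", "specificity"))

    def test_balanced_accuracy_is_mean_of_sens_spec(self):
        class M:
            def predict_logits(self, x):
                n = len(x)
                return np.asarray(x).reshape(n, -1)[:, :2]
        # craft logits: sensitivity 80%, specificity 60%
        vols = np.zeros((10, 1, 2))
        labels = np.array([1] * 5 + [0] * 5)
        vols[:4, 0] = [0, 1]      # 4 of 5 positives right
        vols[4, 0] = [1, 0]
        vols[5:8, 0] = [1, 0]     # 3 of 5 negatives right
        vols[8:, 0] = [0, 1]
        m = M()
        metrics = evaluate(m, vols, labels)
        assert metrics["sensitivity"] == pytest.approx(80.0)
        assert metrics["specificity"] == pytest.approx(60.0)
        assert metrics["balanced_accuracy"] == pytest.approx(70.0)

    def test_random_scores_give_chance_auc(self):
        class M:
            def __init__(self):
                self.rng = np.random.default_rng(0)
            def predict_logits(self, x):
                return self.rng.standard_normal((len(x), 2))
        vols = np.zeros((2000, 2, 2, 2))
        labels = np.tile([0, 1], 1000)
        metrics = evaluate(M(), vols, labels)
        assert abs(metrics["auc_roc"] - 50.0) < 3.0

    def test_single_class_set_has_no_auc(self):
        vols = np.full((4, 2, 2, 2), 1.0)
        labels = np.ones(4, dtype=int)
        metrics = evaluate(self._perfect_model(), vols, labels)
        assert metrics["auc_roc"] is None
        assert metrics["sensitivity"] == pytest.approx(100.0)

    def test_permutation_invariance(self, rng):
        class M:
            def predict_logits(self, x):
                s = np.asarray(x).mean(axis=(1, 2, 3, 4))
                return np.stack([-s, s], axis=1)
        vols = rng.random((20, 4, 4, 4)) - 0.5
        labels = (vols.mean(axis=(1, 2, 3)) + rng.normal(0, .1, 20) > 0).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        base = evaluate(M(), vols, labels)
        perm = rng.permutation(20)
        assert evaluate(M(), vols[perm], labels[perm]) == base


def _tiny_setup(n=16, seed=0):
    """A small full-resolution dataset with a label-balanced split."""
    from pifnet.synthetic import SyntheticSpec, generate

    data = generate(SyntheticSpec(n_per_class=n // 2, seed=seed))
    idx0 = np.where(data.labels == 0)[0]
    idx1 = np.where(data.labels == 1)[0]
    split = (np.concatenate([idx0[:5], idx1[:5]]),
             np.concatenate([idx0[5:7], idx1[5:7]]),
             np.concatenate([idx0[7:], idx1[7:]]))
    return data, split


class TestTrain:
    def test_constant_series_stops_patience_after_first(self):
        """Zero learning rate freezes the model: the validation series is
        constant and training stops exactly `patience` evaluations after the
        first one."""
        data, split = _tiny_setup()
        h = build_model("A", data.shape, seed=0, width=0.25)
        hp = {"learning_rate": 0.0, "batch_size": 4, "patience": 5}
        rec = train(h, data.volumes, data.labels, split, hp,
                    np.random.default_rng(0), max_epochs=50,
                    use_augmentation=False)
        assert len(set(rec.val_series)) == 1
        assert rec.stop_iteration == 1 + 5

    def test_cap_limits_iterations(self):
        data, split = _tiny_setup()
        h = build_model("A", data.shape, seed=0, width=0.25)
        hp = {"learning_rate": 1e-3, "batch_size": 4, "patience": 50}
        rec = train(h, data.volumes, data.labels, split, hp,
                    np.random.default_rng(0), max_epochs=3,
                    use_augmentation=False)
        assert rec.stop_iteration == 3
        assert len(rec.val_series) == 3

    def test_full_protocol_determinism(self):
        """The seed quadruple reproduces every number in the record."""
        results = []
        for _ in range(2):
            data, split = _tiny_setup(seed=1)
            h = build_model("A", data.shape, seed=2, width=0.25)
            hp = {"learning_rate": 1e-3, "batch_size": 4, "patience": 3}
            rec = train(h, data.volumes, data.labels, split, hp,
                        np.random.default_rng(3), max_epochs=6)
            results.append(rec)
        assert results[0].val_series == results[1].val_series
        assert results[0].stop_iteration == results[1].stop_iteration
        assert results[0].test_metrics == results[1].test_metrics

    def test_record_invariants(self):
        data, split = _tiny_setup()
        h = build_model("A", data.shape, seed=0, width=0.25)
        hp = {"learning_rate": 1e-3, "batch_size": 4, "patience": 2}
        rec = train(h, data.volumes, data.labels, split, hp,
                    np.random.default_rng(0), max_epochs=30,
                    use_augmentation=False)
        assert len(rec.val_series) == rec.stop_iteration
        assert all(0 <= v <= 100 for v in rec.val_series)
        assert rec.stop_iteration >= hp["patience"]


class TestConvergenceReport:
    def _rec(self, split_id, stop, fam_seed=0):
        return TrialRecord(split_id=split_id, seed=fam_seed,
                           hyperparams={}, val_series=[50.0] * stop,
                           stop_iteration=stop, wallclock_s=1.0,
                           test_metrics={"balanced_accuracy": 90.0})

    def test_identical_families_have_zero_difference(self):
        records = {
            "baseline": [self._rec(i, 10) for i in range(3)],
            "pif": [self._rec(i, 10) for i in range(3)],
        }
        df = convergence_report(records)
        assert len(df) == 2
        assert df.attrs["paired_iteration_diff_pif_minus_baseline"] == [0, 0, 0]

    def test_row_per_family_and_se(self):
        records = {
            "baseline": [self._rec(i, s) for i, s in enumerate((8, 10, 12))],
            "pif": [self._rec(i, s) for i, s in enumerate((6, 8, 10))],
            "patch_based": [self._rec(i, s) for i, s in enumerate((20, 22, 24))],
        }
        df = convergence_report(records)
        assert len(df) == 3
        base = df[df.family == "baseline"].iloc[0]
        assert base.stop_iteration_mean == pytest.approx(10.0)
        assert base.stop_iteration_se == pytest.approx(2.0 / np.sqrt(3))
        assert df.attrs["paired_iteration_diff_pif_minus_baseline"] == [-2, -2, -2]

    def test_mismatched_split_ids_rejected(self):
        records = {
            "baseline": [self._rec(i, 10) for i in range(3)],
            "pif": [self._rec(i + 1, 10) for i in range(3)],
        }
        with pytest.raises(ValueError, match="split ids"):
            convergence_report(records)

    def test_minimum_family_and_record_counts(self):
        with pytest.raises(ValueError, match="two model families"):
            convergence_report({"baseline": [self._rec(0, 5)] * 3})
        with pytest.raises(ValueError, match="fewer than 3"):
            convergence_report({"baseline": [self._rec(0, 5)] * 3,
                                "pif": [self._rec(0, 5)]})
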